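# tmgdx

Tensiomyography (TMG) twitch analysis and bilateral-asymmetry diagnostics
for muscle-injury screening.

TMG measures the radial displacement of a muscle belly during an
electrically evoked isometric twitch.  Three parameters summarise a twitch:
the delay time **Td** (stimulus → 10 % of peak), the contraction time
**Tc** (10 % → 90 % of peak) and the maximal displacement **Dm**.  After an
acute hamstring (biceps femoris) injury the injured leg's Tc lengthens
markedly while Dm barely changes, so the *bilateral asymmetry* of Tc is a
candidate screening statistic.  For a pair of parameter values (a, b) from
a subject's two legs, the asymmetry score is the symmetric absolute
percentage difference

    diff% = ( |a − b|/b + |a − b|/a ) · 100 / 2 ,

with (a, b) = (injured leg, contralateral leg) in injured subjects and
(left, right) in non-injured subjects.  The package evaluates diff% as a
one-dimensional classifier of injury status: empirical ROC with AUC
(rank/trapezoidal form), DeLong and Hanley–McNeil standard errors, the
Youden-optimal cut-off J = max(sens + spec − 1) with stratified-bootstrap
confidence intervals, precision–recall analysis (average precision, F1max,
PPV/TPR), a Monte-Carlo Cramér's V association test, and noncentral-t
power analysis.  Because no raw cohort of this kind is public, a
synthetic-cohort generator reproduces the reference study design
(53 injured / 53 non-injured athletes, 22 F + 31 M per group) with
configurable interlimb correlation; see `docs/methods.md` for the model
and its calibration.

## Worked example

```python
from tmgdx import AnalysisConfig, run_full_analysis

report = run_full_analysis(AnalysisConfig(seed=1))
roc = report.roc["tc"]["all"]
print(f"Tc AUC      {roc['auc']:.3f} ± {roc['se_auc']:.3f} ({roc['se_method']})")
print(f"Youden J    {roc['youden_j']:.3f} at cut-off > {roc['cutoff']:.2f}%")
print(f"sens/spec   {100*roc['sens_at_cutoff']:.1f}% / {100*roc['spec_at_cutoff']:.1f}%")
print(f"Tc AUPRC    {report.prc['tc']['all']['auprc']:.3f}")
print("power (d=0.2/0.5/0.8):",
      " ".join(f"{row['power']:.3f}" for row in report.power))
```

prints

```
Tc AUC      0.970 ± 0.015 (delong)
Youden J    0.887 at cut-off > 9.41%
sens/spec   92.5% / 96.2%
Tc AUPRC    0.978
power (d=0.2/0.5/0.8): 0.175 0.722 0.983
```

Reading: on a simulated reference cohort the Tc asymmetry score separates
injured from non-injured subjects with AUC ≈ 0.97 — a subject whose Tc
asymmetry exceeds ≈ 9–13 % is flagged as injured, catching ≈ 9 in 10
injured subjects while mis-flagging ≈ 1 in 25 controls.  Td and Dm
asymmetries (also in the report) discriminate far less well, and the power
column reproduces the two-sample t-test power of the 53-per-group design.

The same pipeline runs from a shell:

```
tmgdx simulate --seed 1 --out cohort.csv
tmgdx analyze --cohort cohort.csv --seed 1 --out analysis/
tmgdx extract --in waveforms/ --out params.csv   # raw twitch files
```

Estimator-style entry points are available for sklearn composition:
`YoudenCutoffClassifier` (fit scores → `cutoff_`, `auc_`, `youden_j_`;
predict thresholds new scores) and `TwitchParamExtractor` (waveforms →
(Td, Tc, Dm) feature matrix).

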