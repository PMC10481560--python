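# rectarc

Automated single-arc VMAT planning, dosimetric evaluation and QA for
locally advanced rectal cancer — at desk scale, on a synthetic pelvic
phantom.

Clinical VMAT planning for rectal cancer is slow and planner-dependent:
the planning target volume (PTV) wraps posteriorly around the bladder and
small bowel, and meeting the coverage goal (D93 > 98 % of prescription)
while sparing those organs takes repeated manual optimization.  `rectarc`
implements a fully scripted planning workflow that removes the manual
steps: it checks the contoured structure names, inserts a virtual couch,
derives the optimization help structures automatically (organ-at-risk
volumes minus the PTV, an abdominal-direction "bowel-bag"-like control
shell), builds the objective list with a dose fall-off term per organ at
risk, optimizes a single 360° coplanar arc in staged passes (two initial
passes, hotspot extraction, three correction passes, PTV-coverage
constraint escalation), sequences the fluence into MLC apertures, and
evaluates the result against a clinical goal list.

The evaluation stack is complete and usable on its own:

* cumulative DVHs with Dx / Vx / Dmax / Dmean readout,
* conformity index `CI = TV_PIV² / (TV × PIV)` and homogeneity index
  `HI = (D2 − D98) / D_prescription`,
* plan sums for composite organ-at-risk evaluation,
* gamma analysis (3 % / 2 mm, global normalisation, 10 % cutoff),
* the VMAT modulation complexity score (MCS ∈ [0, 1]) and total MU,
* an exact two-sided Wilcoxon signed-rank test for paired cohorts.

Because patient CT data are not required, the package ships a seeded
generator of synthetic pelvic phantoms with the anatomy the planner
assumes: an elliptical water-equivalent body, a concave 600–1400 cm³
initial PTV, an interior boost PTV, a full bladder abutting/overlapping
the PTV anteriorly, small bowel anterior–superior and two femoral heads.

## Worked example

```python
from rectarc import AutoPlanConfig, PhantomSpec, generate_phantom, run_autoplan
from rectarc.io import default_goals

density, structs = generate_phantom(PhantomSpec(seed=42))
result = run_autoplan(density, structs, default_goals(), AutoPlanConfig())

m = result.artifacts["initial"].metrics
print(f"PTV-initial D93 = {m['D93_pct']:.1f} %  D2 = {m['D2_pct']:.1f} %")
print(f"CI = {m['CI']:.2f}  HI = {m['HI']:.3f}  MCS = {m['MCS']:.2f}")
print("all goals met:", result.goal_report.ok)
```

On the packaged phantom this prints (the initial 45 Gy plan):

```
PTV-initial D93 = 99.4 %  D2 = 102.1 %
CI = 0.57  HI = 0.030  MCS = 0.22
all goals met: True
```

D93 = 99.4 % means 93 % of the PTV receives at least 99.4 % of the 45 Gy
prescription — the coverage goal (> 98 %) is met; D2 (the near-maximum
dose) stays well below the 110 % limit.  The goal report also checks the
plan sum of the initial and boost plans against the organ-at-risk limits
(small-bowel V35/V40/V45 in cc, bladder and femoral-head V40/V45/V50 in %
volume); a violation inside the PTV-overlap region is flagged rather than
failed, mirroring clinical practice for targets that invade the organ.

The same pipeline is scriptable from the shell:

```bash
rectarc phantom --seed 42 --out ph/
rectarc autoplan --phantom ph/ --out plan/
rectarc evaluate --dose plan/dose_sum.nrrd --structures plan/structures \
                 --rx 50.4 --scope plan_sum --out eval/
rectarc qa --plan-dir plan/ --out qa.json
rectarc compare --a cohortA.csv --b cohortB.csv --out compare.csv
```

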