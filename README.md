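# cfams — CFA with mean structure and the recovery of weak factor loadings

`cfams` is a simulation and analysis toolkit for a question that matters to
psychometricians and methodologists fitting confirmatory factor analysis
(CFA) models with *weak factors* (loadings around 0.30, as arise for traits
low in a hierarchy of abilities or for low-communality item sets): **does
jointly modeling the observed-variable means improve the estimation of weak
loadings, compared to analyzing the covariance structure alone?**

The covariance model and its mean extension are

    Σ = Λ Φ Λ′ + Θδ,        μ = τ + Λ κ,

with Λ the p×q loadings, Φ the factor covariances, Θδ the unique variances,
τ the item intercepts and κ the factor means. Adding a *non-saturated* mean
structure with κ ≠ 0 contributes net Fisher information about the
covariance parameters — the Schur complement I*θθ − Iθν Iνν⁻¹ Iνθ with
I*θθ = (κκ′)⊗Σ⁻¹ on the loading block — and therefore reduces the
asymptotic variances of loading estimates. The package implements:

* the three benchmark population models (12 standardized indicators; one,
  two or three factors, exactly one of them weak) and their mean-structure
  constraint patterns C1 (saturated), C2 (tau-equivalent: all τ = 0),
  C3–C5 (one factor's intercepts zeroed);
* seeded multivariate-normal data generation from the model-implied moments;
* ML and ULS estimation of CFA and CFA-MS models via Fisher scoring, with a
  250-iteration cap, Heywood-case detection and standardized solutions;
* the information calculus: Ic, added/net information, asymptotic
  covariances with and without means, and analytic and empirical ARE
  (asymptotic relative efficiency: Var(√n λ̂) with means over without;
  values < 1 favor modeling means);
* RMSD recovery scoring (√(Σ(λ(t)−λ(e))²/p), satisfactory below 0.20);
* the full factorial Monte Carlo study (156 design cells: method × N ∈
  {100, 300, 500} × constraint × factor correlation 0/0.5) with
  paired-seed CFA/CFA-MS fits and per-cell summaries;
* a factorial ANOVA metamodel (main effects + two-way interactions)
  reporting partial η² per effect with Cohen-style bands.

See `docs/methods.md` for the model, algorithms and design choices.

## Worked example

Run the one-factor arm of the study (all 12 loadings 0.30 — the pure
weak-factor case) at 50 replications per cell:

```python
from cfams import StudyConfig, run_study

res = run_study(StudyConfig(reps_per_cell=50, master_seed=20160105,
                            model_ids=("1F",)))
cols = ["method", "N", "constraint", "n_valid", "rmsd_mean", "are_mean"]
print(res.cells[res.cells.method == "ML"][cols].round(4).to_string(index=False))
```

```
method   N constraint  n_valid  rmsd_mean  are_mean
    ML 100       NONE       50     0.1368       NaN
    ML 100         C1       50     0.1347    0.9648
    ML 100         C2       50     0.0424    0.1199
    ML 100         C3       50     0.1007    0.5998
    ML 300       NONE       50     0.0761       NaN
    ML 300         C1       50     0.0761    1.0002
    ML 300         C2       50     0.0211    0.0936
    ML 300         C3       50     0.0576    0.5810
    ML 500       NONE       50     0.0577       NaN
    ML 500         C1       50     0.0577    1.0002
    ML 500         C2       50     0.0168    0.1005
    ML 500         C3       50     0.0454    0.6216
```

Reading the table: `NONE` is covariance-only CFA; its weak-loading RMSD
shrinks like 1/√N. The saturated mean structure C1 changes nothing (ARE ≈ 1
— saturated means carry no net information). The tau-equivalent constraint
C2 is dramatic: loading variance drops to about a tenth (ARE ≈ 0.10,
matching the analytic value 0.087 from `analytic_are`), and recovery is
satisfactory (RMSD < 0.20) even at N = 100. C3 sits in between. The same
engine exposes the closed-form side:

```python
from cfams import make_model, constraint_pattern, analytic_are
analytic_are(make_model("1F"), constraint_pattern("1F", "C2")).round(4)
# array([0.0867, 0.0867, ..., 0.0867])
```

A command-line interface wraps the same functionality:

```sh
cfams simulate --reps 100 --models 1F,2F,3F --out results/
cfams analyze --replicates results/replicates.csv --out results/
cfams are --model 1F --constraint C2
cfams run --config study.yaml --out results/
```

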