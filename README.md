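# lbdgrad

Cortical connectivity gradients across the Lewy body disease spectrum:
diffusion-map embedding of parcellated connectomes, group comparison of
gradient distributions and regional scores, a composite
gradient-difference severity score, spin-permutation spatial nulls, and
imaging-transcriptomics PLS — with a synthetic-cohort generator that
plants the hypothesised disease effects so the whole pipeline is testable
without restricted imaging data.

## The problem

Lewy body diseases span Parkinson's disease with intact cognition (PD-NC)
and Lewy body dementia (LBD). Cortical *gradients* — eigenvector
decompositions of region-by-region connectivity similarity — summarise
each brain's large-scale organisation as a score per region along
continuous axes. Disease can alter those axes in qualitatively different
ways: **expansion** (scores spread away from the centre; regions become
more differentiated), **contraction** (the converse), or
**reorganisation** (individual regions change rank while the overall
distribution looks normal). Distinguishing these patterns, and relating
them to severity, cell-type topographies and gene expression, is the
analysis this package implements.

For each subject the pipeline computes, from a 200-parcel connectivity
matrix `X`:

1. row sparsification (keep the top 10% of weights per row),
2. the normalised-angle affinity `A(i,j) = 1 − arccos(cossim(x_i, x_j))/π`,
3. diffusion-map embedding of `A` (α = 0.5, 10 components,
   scores scaled by λ/(1−λ)) — G1 is the principal gradient,
4. orthogonal Procrustes alignment to a control-group template.

Groups are compared at the distribution level (Kruskal–Wallis on the
per-subject SD of G1 scores, Dunn post-hoc) and regionally (per-parcel OLS
with age and sex covariates; BH-FDR). Per subject, the composite gradient
difference score

    Gs = Σ_regions |x − μ_HC| / σ_HC

measures how deviant a subject's organisation is from controls and is
rank-correlated with clinical severity. Regional t-maps are contextualised
against annotation maps (pooled cell-type marker expression, axes,
disease gene sets) and against a region×gene expression matrix via PLS;
all spatial inference uses spin permutations (hemisphere-mirrored random
rotations of the parcel sphere, 1000 per test) with family-wise FDR
(`q_spin`).

See `docs/methods.md` for the model, the synthetic generator and every
numerical choice.

## Worked example

```python
from lbdgrad import AnalysisConfig, make_cohort
from lbdgrad.gradients import embed_cohort
from lbdgrad.compare import kruskal_wallis, spread_stats

config = AnalysisConfig(n_components=10)
cohort, template, latent = make_cohort(seed=0)          # 23 HC / 46 PD-NC / 62 LBD
_, aligned = embed_cohort(cohort.matrices, cohort.subjects_in("HC"), config)
spread = spread_stats(aligned).merge(cohort.table[["subject_id", "group"]],
                                     on="subject_id")
kw = kruskal_wallis(spread["spread_sd"].to_numpy(), spread["group"].to_numpy())
print(f"H = {kw.h:.2f}, p = {kw.p:.3g}")
```

```
H = 77.88, p = 1.23e-17
```

The default cohort plants expansion (γ = 1.3) in PD-NC and regional
reorganisation (30% of parcels) in LBD. The Kruskal–Wallis on the spread
of aligned G1 scores picks up the expanded PD-NC group; the Dunn post-hoc
from the same run localises it (HC vs PD-NC z = −5.48, q = 6e-8) while
LBD is indistinguishable from controls at the distribution level
(z = +1.13, q = 0.26) — yet the regional model finds 43 parcels at
q < 0.05 in LBD vs HC, the planted dissociation between distribution-level
normality and regional reorganisation.

The same chain is scripted as a narrative analysis under `analysis/`
(`01_simulate.py` … `06_transcriptomics.py`), each step writing its tables
to `results/` and printing what it found, and as a CLI:

```bash
lbdgrad simulate --out sim/ --seed 0
lbdgrad gradients --matrices sim/matrices --cohort sim/cohort.tsv --out grads/
lbdgrad compare --gradients grads/ --cohort sim/cohort.tsv --out cmp/
```

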