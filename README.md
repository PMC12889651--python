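# ctmd

Rank protein–ligand pose stability with short, unconverged well-tempered
metadynamics runs — and evaluate how well that ranking enriches true
binders at the top of a virtual screen.

`ctmd` is aimed at computational chemists triaging hits after docking:
methods that are cheap (docking scores) rank poorly among the top few
candidates, and methods that rank well (absolute binding free energy
calculations) are too expensive for hundreds of ligands. The CTMD score
sits in between. It needs only a handful of short metadynamics runs per
ligand and no converged free-energy surface.

This package implements the scoring method and its evaluation protocol on
a self-contained 1D toy model (no MD engine required), and reads/writes
PLUMED-format HILLS files so the same estimator can be applied to hills
logged by real production runs.

## The method

A well-tempered metadynamics run biases a collective variable *s* — the
ligand's RMSD from its docked pose — by depositing Gaussian hills whose
heights decay as the bias *V*(*s*, *t*) accumulates (bias factor γ > 1).
From the bias alone one can evaluate the reversible-work estimator

```
c(t) = (1/β) · log [ ∫ ds exp( γ/(γ−1) · βV(s,t) )  /  ∫ ds exp( 1/(γ−1) · βV(s,t) ) ]
```

c(t) starts at zero and climbs as tempered bias piles up where the system
actually is. A stable pose traps the walker in its RMSD well, so bias
concentrates and the terminal c(t) is high; an unstable pose escapes
early, the bias spreads thin, and terminal c(t) stays low. The **CTMD
score** of a ligand is the *minimum over a few independent replicas*
(default 3) *of the terminal c(t)* — conservative on purpose: one early
escape marks the pose unstable. Higher score ⇒ more stable pose ⇒
predicted binder.

Rankings are evaluated with the standard early-enrichment metrics:

- **EF_xx** — hit density in the top xx% of the ranking over the base hit
  rate (EF100 ≡ 1; values > 1 beat random),
- **BEDROC(α)** — exponentially weights early ranks (α = 20 by default),
- **binder subsampling** — repeatedly draw k binders with replacement
  against the fixed non-binder set to emulate realistic (~16%) hit rates
  and get percentile confidence bands.

The built-in synthetic screen gives each toy ligand a latent Gaussian-well
depth (binders deeper than non-binders), runs the whole pipeline, and asks
whether CTMD recovers the planted ranking.

## Worked example

Simulate a small screen (2 binders with ~8 kT wells, 3 non-binders with
~2 kT wells, 3 replicas each, 100k steps per replica):

```
$ ctmd simulate --binders 2 --nonbinders 3 --n-steps 100000 --seed 7 --out demo
wrote 5 score rows and 15 HILLS files to demo

$ cat demo/screen.csv
ligand_id,score,label,well_depth,ct_terminal_0,ct_terminal_1,ct_terminal_2
B001,3.314844309673811,binder,8.318891135148299,3.9094617643393397,3.62625149473842,3.314844309673811
B002,4.0137940175926,binder,9.265834339532766,4.7723660492925015,4.097035160031932,4.0137940175926
N001,1.4555840530942707,nonbinder,1.302784047915193,1.4555840530942707,1.5696916300818566,1.5315897255553974
N002,1.4723695640558265,nonbinder,1.5213324979324732,1.4723695640558265,1.584836179222735,1.6420652337108206
N003,1.6079282247488171,nonbinder,3.157324622000455,1.9109794603824986,1.8358880102985289,1.6079282247488171
```

Both deep-well binders out-score all three shallow-well non-binders: the
scores (minimum terminal c(t) across the three replicas, in kT) cleanly
separate at ≈ 3.3–4.0 vs ≈ 1.5–1.6. The same score can be recomputed from
the HILLS files alone:

```
$ ctmd score --hills demo/B001/HILLS.0 --hills demo/B001/HILLS.1 --hills demo/B001/HILLS.2 --ligand-id B001
{"ligand_id": "B001", "score": 3.3148443100289198, "per_replica_terminal_ct": [3.9094617644218754, 3.6262514946664046, 3.3148443100289198]}
```

and the c(t) trace of any single run inspected with
`ctmd ct --hills demo/B001/HILLS.0`. The files are plain PLUMED dialect
(`time cv sigma_cv height biasf`, heights in kJ/mol), so `--hills` can
point at hills logged by a real metadynamics engine instead.

`ctmd run --out DIR` executes the full demo pipeline (simulate → score →
subsampled enrichment) from a YAML config; `ctmd enrich table.csv` scores
any external `ligand_id,score,label` (or `pki`) table.

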