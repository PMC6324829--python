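# jemge — joint evolutionary models for the genome and the epigenome

`jemge` is a likelihood framework for a central question of comparative
epigenomics: when a histone modification differs between two species on
homologous DNA, does that epigenomic change depend on the local sequence
changes — and if so, on substitutions, on insertions/deletions (indels), or
on both?

It is aimed at researchers with pairs of homologous regions (e.g. built from
ChIP-seq peaks lifted between two genomes) who want to move beyond ad-hoc
overlap statistics to explicit evolutionary model comparison.

## The model

The observed unit is a *homologous pair* `(A, B)`: two genomic regions of
lengths `s_A`, `s_B`, each carrying binary tracks (1 inside a peak, 0
outside) for `H` histone marks.  The joint probability sums over unobserved
alignments (*paths*):

    P(A, B) = Σ_path P(path) · Π_h P(A^h, B^h | path)

with `P(path)` given by the TKF91 birth–death indel model (insertion rate
λ, deletion rate μ, λ tied to μ through the pair lengths as
λ = μ(s_A+s_B)/(s_A+s_B+2)), nucleotide substitution by a reversible
one-rate (F81-type) kernel with rate `s`, and each mark by a two-state
switch process with rate `κ_h` and equilibrium on-probability `π1_h`:

    g_xy(t) = e^{−κt}·1[x=y] + π_y(1 − e^{−κt}),     t ≡ 1.

Four hypotheses about how mark changes relate to sequence changes give four
conditional models for the per-column mark probabilities:

| model | substitutions | indels | mismatch columns | indel columns |
|-------|---------------|--------|------------------|---------------|
| N     | independent   | independent | switch kernel g | local equilibrium Φ |
| M     | dependent     | independent | global equilibrium π | local equilibrium Φ |
| I     | independent   | dependent   | switch kernel g | global equilibrium π |
| B     | dependent     | dependent   | global equilibrium π | global equilibrium π |

The alignment sum is computed exactly by an `O(s_A·s_B)` scaled dynamic
program.  The package provides simplex (Nelder–Mead) maximum-likelihood
estimation of `θ = (μ, s, κ)`, a four-component EM mixture over the models,
per-region classification by largest likelihood, and the normalized
contrasts `r_ind` and `r_mut` that quantify how much better the
indel-dependent (resp. substitution-dependent) side fits each region.  A
simulator generates datasets faithful to each hypothesis for calibration
and power studies.

## Worked example

Simulate 50 pairs of 200-bp homologous regions under Model I (mark changes
depend on indels only) with μ = 0.1, s = 0.1, κ = 1, then fit Model I:

```python
from jemge import (SimulationConfig, simulate_dataset, build_dataset,
                   fit_mle, ModelKind, ThetaFree, percent_error)

theta = ThetaFree(mu=0.1, s=0.1, kappa=(1.0,))
cfg = SimulationConfig(model=ModelKind.I, theta=theta,
                       ancestor_length=200, n_pairs=50, seed=42)
sims, manifest = simulate_dataset(cfg)
ds = build_dataset([s.pair for s in sims])
fit = fit_mle(ds, ModelKind.I)
print(fit.theta_hat)
print({k: round(v, 1) for k, v in percent_error(fit.theta_hat, theta).items()})
```

prints (seed 42):

```
ThetaFree(mu=0.10527784171776501, s=0.10419564720411949, kappa=(0.9992824476602322,))
{'mu': 5.3, 's': 4.2, 'kappa_1': -0.1}
```

i.e. the deletion, substitution and switch rates are recovered within a few
percent of the generating values at this reduced sample size.  The same
pipeline is available from the shell:

```sh
jemge simulate --model I --mu 0.1 --s 0.1 --kappa 1 \
    --n-pairs 50 --length 200 --seed 42 --out bundle/
jemge estimate --bundle bundle/ --model I --out fit_I.json
jemge classify --bundle bundle/ --fit N=fit_N.json --fit M=fit_M.json \
    --fit I=fit_I.json --fit B=fit_B.json --out regions.tsv
jemge metrics --results regions.tsv --out regions_r.tsv
```

`classify` writes one row per region with the four log-likelihoods, the
best model, and `r_ind`/`r_mut` under both normalizations; `metrics` prints
the quadrant summary of the (r_ind, r_mut) scatter.

Real data enter through `jemge estimate --fasta-a A.fa --fasta-b B.fa
--bed peaksA.bed,peaksB.bed`: paired FASTA records (one per region, matched
by id) plus region-relative BED peak intervals per mark and species.

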