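# sizesel

Joint maximum-likelihood estimation of **size-selectivity curves** for
gillnets and piscivorous predators from multi-gear length-frequency catch
data, with overlap summaries that quantify how strongly a predator and a
fishery compete for the same fish sizes.

The package is aimed at fisheries scientists and ecologists who have
catch-at-length tables from several capture methods at once — a fleet of
gillnets with different mesh sizes, plus one or more predators whose diet
has been reconstructed (e.g. from regurgitated pellets) — and who want
selectivity parameters for all of them from a single estimation, without
assuming the methods have comparable fishing effort.

## Model

For gear *i* and 1-cm length class *j*, catches are modelled as
independent Poisson counts

    n_ij ~ Poisson( f_i · μ_j · S_ij(θ) )

where μ_j is the relative abundance of class *j* in the sampled
population, S_ij the gear's selectivity at that length and f_i its
fishing power. Because fishing power changes only a gear's sample size and
not the length distribution *within* its sample, each gear's column can be
normalised to frequencies and f_i drops out of the problem. With powers
fixed at 1 the abundances maximise out in closed form,
μ_j = Σ_i n_ij / Σ_i S_ij, leaving a profile log-likelihood

    ℓ(θ) = Σ_ij [ n_ij ln(μ_j S_ij) − μ_j S_ij ]

over just four parameters:

* **Mesh nets** — gamma densities rescaled to modal value 1. Under
  *geometric similarity* the modal length is proportional to mesh size,
  mode_i = θ₁·m_i, and all nets share one curve variance θ₂ = α_i β_i²;
  the per-net gamma shape (α_i, β_i) follows from these two constraints.
* **Predator** — a lognormal density rescaled to modal value 1, with
  log-location θ₃ and log-spread θ₄; its mode is exp(θ₃ − θ₄²).

ℓ(θ) is maximised by Nelder–Mead in log-parameter space; standard errors
come from the observed information (numerical Hessian). Pairwise
competition between fitted curves is summarised by the overlap
coefficient: 100 × ∫ min(f_a, f_b) dl after normalising each curve to
unit area.

The package ships the Curonian Lagoon European perch dataset (34 length
classes, eight gillnets of 14–45 mm mesh and Great Cormorants; 4663 fish)
as a bundled fixture, a Poisson catch simulator for parameter-recovery
and calibration studies, and a small CLI (`sizesel fit|overlap|simulate`).

## Worked example

```python
from sizesel import SelectivityModel, load_perch_catches

res = SelectivityModel(load_perch_catches()).fit()
print(res.summary())
```

```
         Selectivity Model Results
==============================================
Gears: 9 (8 mesh, 1 predator)   Length classes: 34
Normalized frequencies: True
Log-likelihood kernel: -31.9907
Converged: True   Evaluations: 711
----------------------------------------------
param     estimate   std err  unit
theta1      0.7071    0.0467  cm/mm
theta2     12.9324    7.2280  cm^2
theta3      2.1251    0.4255  log-cm
theta4      0.4088    0.3659  -
==============================================
```

The 14 mm net therefore peaks at θ₁·14 ≈ 9.9 cm and the cormorant curve
at exp(θ₃ − θ₄²) ≈ 7.1 cm — cormorants take mostly smaller perch than
even the finest net. The overlap coefficients make that concrete:

```python
print(res.overlap("GC", "G14").overlap_pct)   # 73.3  (strong overlap)
print(res.overlap("GC", "G38").overlap_pct)   # 2.7   (negligible)
```

Cormorant predation overlaps heavily (≈73%) with the smallest,
non-commercial mesh but barely (≈2.7%) with the 38 mm net, and the two
curves cross at ≈19 cm, right around the 18 cm minimum legal size —
i.e. the birds and the commercial fishery largely target different parts
of the stock.

The same analysis from the shell:

```sh
sizesel fit --demo --out-dir out/
sizesel overlap out/fit.json --all --plot out/curves.png --out-dir out/
```

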