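# rubiscan

Analysis pipeline for a growth-coupled **deep mutational scan (DMS) of
rubisco**, the CO₂-fixing enzyme.  In the assayed system an engineered
*E. coli* strain grows on glycerol only when rubisco carboxylation carries
flux, so the relative growth rate of each of thousands of barcoded
single-amino-acid variants — read out as barcode counts before and after
selection — reports enzyme activity.  Repeating the selection across a CO₂
titration lets one infer, for every variant, an effective maximal-velocity
ratio Ṽ_max and CO₂ affinity K̃_C.

The package is aimed at DMS practitioners and enzyme engineers who want a
tested, ground-truthed implementation of this inference: every stage runs
on synthetic data with known kinetics, so recovery can be measured rather
than assumed.

## The statistics at the core

Per-variant enrichment (median over barcodes i passing
max(N₀,ᵢ, N_f,ᵢ) ≥ c_min):

    e_j = median_i [ log₁₀((N_f,i + N_f,tot·α_p)/(N₀,i + N₀,tot·α_p))
                     − log₁₀(N_f,tot / N₀,tot) ]

normalized so that wild type = 1 and the median of a catalytic dead panel
= 0.  Under growth-coupled selection the normalized enrichment equals
v_mut/v_WT in expectation, so across a CO₂ titration

    e_norm([CO₂]) = (Ṽ_max,mut/Ṽ_max,WT) · (K_C,WT + [CO₂]) / (K_C,mut + [CO₂])

with K_C,WT = 149 μM.  Each variant is refit over an 11×10 grid of the
processing parameters (c_min, α_p) × 10 replicate subsamplings — 1,100
bootstrap fits — and flagged *reliable* when the quartile-based
coefficient of variation of K̃_C is below 1.

## Worked example

```python
import rubiscan as rb

# a small library with known ground truth: 209 designed variants,
# dead panel at position 5, 10 barcodes/variant
design = rb.make_design(length=12, seed=3)
config = rb.SimulationConfig(seed=4, barcodes_per_variant=10,
                             read_depth=200_000, dead_positions=(5,))
variants, barcodes = rb.generate_library(design, config)
counts = rb.simulate_selection(variants, barcodes,
                               rb.default_conditions(replicates=3), config)

dead = rb.dead_variant_ids(variants)
fits = rb.reliability_sweep(counts, dead, rb.FitConfig.reduced(seed=7))
vid = "R2F"
truth = variants.set_index("variant_id").loc[vid]
fit = fits.set_index("variant_id").loc[vid]
print(f"{vid}: true K_C = {truth.true_kc_um:.0f} uM, "
      f"inferred K_C = {fit.kc_um:.0f} uM (CV {fit.cv:.2f}, "
      f"reliable={fit.reliable})")
```

prints

```
R2F: true K_C = 486 uM, inferred K_C = 497 uM (CV 0.10, reliable=True)
```

i.e. the titration fit recovers this variant's ~3-fold-impaired CO₂
affinity within a few percent, and the bootstrap marks the estimate
trustworthy.

## Analysis drivers

Numbered scripts under `analysis/` run the full narrative and write their
tables under `results/` (regenerated on demand, not shipped):

| script | what it does |
|---|---|
| `01_simulate_library.py` | 551-variant ground-truth library, 3 replicates × 6 CO₂ levels, 10⁶ reads/condition/timepoint |
| `02_map_barcodes.py` | long-read consensus mapping of ~1,000 barcodes at 10% read error (accuracy vs truth) |
| `03_enrichment.py` | (c_min, α_p) sweep by replicate correlation; normalized enrichments |
| `04_titration_fit.py` | reliability-swept Michaelis–Menten fits; K̃_C recovery vs ground truth |
| `05_conservation.py` | synthetic family alignment; conservation vs positional fitness |
| `06_invitro_kinetics.py` | absorbance-trace rates, MM fits, CABP k_cat, MIMS S_C/O |

A thin CLI wraps the same library calls: `rubiscan simulate`,
`map-barcodes`, `count`, `enrich`, `fit`, `conserve`, `kinetics`.

## Layout

```
src/rubiscan/      library: design, simulate, barcodes, enrichment,
                   titration, conservation, kinetics, io, cli
analysis/          numbered narrative drivers (write to results/)
scripts/           acceptance.py
tests/             pytest suite (unit, property and end-to-end recovery)
docs/methods.md    model, assumptions, parameter choices, limitations
```
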