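# endosyncom

Screening-to-SynCom analysis for culturable plant endophytes.

Medicinal plants such as *Schisandra sphenanthera* host rich communities of
endophytic bacteria and fungi, and the host's own secondary metabolites —
here a triterpenoid mixture — can selectively promote or inhibit individual
strains.  `endosyncom` implements the full desk side of such a campaign for
microbiome researchers who run it at the bench:

1. **Dose–response classification** — log2 fold changes of endpoint growth
   (OD600 for bacteria, mycelium fresh mass for fungi) against a solvent
   control across a concentration gradient, classifying each strain as
   triterpenoid-promoted (TPB/TPF) or -inhibited (TNB/TNF) from the
   medium-to-high decision concentrations:
   `log2FC = log2(value / control)`, so +1.0 means a two-fold gain.
2. **Binary interaction screening** — the interaction index (II) on three
   plate geometries:
   V-shape bacterial co-culture
   `II = [(D25-EA/D10-EA)/(D25-CA/D10-CA) − 1]·100`,
   fungal dual culture and bacterium-vs-fungus streak
   `II = (S-EA/S-CA − 1)·100`; II > 0 facilitation, II < 0 inhibition.
3. **PGPT trait quantification** — IAA (Salkowski), siderophore (CAS),
   DPPH scavenging `%, = (A_ctrl − A_sample)/A_ctrl·100`, and phosphate
   solubilization via linear standard curves with inverse prediction, plus
   per-strain ability counts.
4. **SynCom construction and pot evaluation** — six rule-based communities
   (CK, AB, AF, ABF, TPB&TPF, TNB&TNF), percent-change outcomes
   `(x̄_T − x̄_B)/x̄_B·100` vs control and vs the full community, chlorophyll
   and metabolite quantification, ANOVA + Duncan letter displays and
   rank-sum comparisons (exact for combined n ≤ 12).

Raw tables for such campaigns are rarely deposited, so a first-class
synthetic-data module generates every input with planted ground truth —
logistic growth with capacity-level compound effects, plate measurements,
colorimetric series, pot phenotypes — making every stage testable without a
download.  See `docs/methods.md` for models, parameters and limitations.

## Worked example

```python
import endosyncom as es

catalog = es.default_catalog()                      # 27 bacteria + 26 fungi
truth = es.reference_profile_truth(catalog, seed=7)    # planted ground truth
dose = es.simulate_dose_response(catalog, truth=truth, noise_sd=0.05, seed=7)
classification, contingency = es.classify_panel(dose, catalog)
print(classification["label"].value_counts().to_dict())
designs = es.build_syncoms(classification, catalog)
print({name: len(d.members) for name, d in designs.items()})
```

prints

```
{'TNF': 15, 'TNB': 14, 'TPB': 13, 'TPF': 11}
{'CK': 0, 'AB': 27, 'AF': 26, 'ABF': 53, 'TPB&TPF': 24, 'TNB&TNF': 29}
```

— 13 bacteria and 11 fungi are promoted by the triterpenoid mixture, 14 and
15 inhibited, and the six synthetic communities size accordingly (the two
class-restricted communities partition the 53-strain full community).
Continuing with the same objects:

```python
raw, standards = es.simulate_pot_experiment(designs, truth, noise_sd=0.1, seed=7)
outcomes = es.evaluate_pot(raw, designs, standards)
print(outcomes.query("phenotype == 'root_length_cm' and design == 'ABF'")
      [["pct_vs_ck", "letter"]].round(2).to_string(index=False))
```

```
 pct_vs_ck letter
    114.89      b
```

— the full community roughly doubles root length relative to uninoculated
controls (planted: +115%), and its Duncan letter separates it from both the
control and the promoted-only community.

The `examples/` directory holds one short narrative script per capability
(dose–response classification, interaction screen, trait screen, pot
evaluation, full pipeline); each prints its numbers with a line on what
they mean.

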