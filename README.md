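# viromix

Integration analysis for paired human intestinal viromes: the same faecal
sample sequenced twice, once after physical virus-like-particle (VLP)
enrichment and once as a bulk whole metagenome (WMS), in a household-matched
case/control cohort. Combining both routes captures extracellular phages and
integrated prophages in one profile; the analytical question is which
viruses — and which predicted bacterial hosts — are unique to patients,
unique to their healthy household controls, or communal.

`viromix` implements that analysis as a tested, reusable library with a thin
CLI, exercisable end-to-end on synthetic data with planted ground truth:

* **vOTU quality filtering and dereplication** — contigs ≥ 1 kbp with
  determined genome completeness ≥ 50 % are greedily clustered into viral
  OTUs at ≥ 95 % average nucleotide identity (ANI) over ≥ 85 % aligned
  fraction (AF) of the shorter sequence, each cluster represented by its
  longest member.
* **Presence calling** — a vOTU is *truly present* in a sample when its
  average read coverage (read count × mean read length / vOTU length) is
  strictly over 10-fold; per dataset each vOTU (and each viral cluster, VC)
  is then case-unique, control-unique, communal, or absent.
* **Cross-dataset matching** — per WMS query vOTU, the best VLP hit
  (max bitscore) must clear e-value ≤ 10⁻⁵, bitscore ≥ 1000, identity ≥ 95 %
  and query coverage ≥ 85 % to count as the same virus seen by both routes.
* **Host association** — host predictions at confidence ≥ 90 are joined with
  presence classes; a host whose present viral partners are all case-unique
  is *exclusively case-associated*.
* **Community statistics** — CLR transform, Shannon, bias-corrected Chao1,
  rarefaction, Bray–Curtis and Jaccard distances, PERMANOVA with
  within-household restricted permutations, and one-way ICC.
* **Power analysis** — for a household-matched pair design with log10
  abundance model `y = μ_g + b_h + δ_g·I(case) + ε`, the paired t-test power
  to detect a fold change `10^δ` at α = 0.001 is simulated over a grid of
  pair counts, with a noncentral-t closed form as cross-check.
* **Synthetic data generator** — every input (contigs with planted
  redundancy, coverage matrices with planted presence classes, host tables
  with one planted exclusive host, household-structured genus counts) is
  produced under one master seed, with truth tables for exact-recovery
  testing.
* **EFM enumeration** — VLP concentrations from epifluorescence per-field
  counts.

## Worked example

How many household-matched pairs would a follow-up study need?

```bash
python examples/06_power_analysis.py
```

```
fold change    2x  power curve {5: 0.001, 10: 0.009, 15: 0.022, 20: 0.057, 30: 0.111, 50: 0.32}
                minimal pairs for 90% power: 122
fold change   10x  power curve {5: 0.049, 10: 0.455, 15: 0.874, 20: 0.985, 30: 1.0, 50: 1.0}
                minimal pairs for 90% power: 16
```

Under the default variance components (between-household SD 0.8, residual
SD 0.5 on the log10 scale), a 10-fold abundance shift in a genus reaches
90 % power at α = 0.001 with 16 household pairs, whereas a two-fold shift
needs 122 — the order-of-magnitude gap that motivates large matched cohorts.

The full pipeline is one call (or `viromix run-all --seed 7 --out run_out`):

```bash
python examples/07_full_pipeline.py
```

```
{
  "votu_venn_vlp": {"case_unique": 30, "communal": 60, "control_unique": 30},
  "vc_venn": {"case_unique": 9, "shared": 20, "control_unique": 10},
  "cross_dataset_matches": 3,
  "host_venn": {"shared": 3, "vlp_only": 4, "wms_only": 3},
  "exclusively_case_hosts": ["Anaerotruncus"],
  "permanova_p": 0.065,
  "icc_richness": 0.791,
  "power_minimal_n": 20
}
```

The run recovers exactly the planted structure: the 30/60/30 unique/communal
Venn per dataset, the three verbatim cross-dataset copies, and the single
host genus linked solely to case-unique viruses. Each stage writes TSV/JSON
outputs plus a manifest of SHA-256 digests; reruns with the same config are
byte-identical.

One narrative script per capability lives in `examples/`.

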