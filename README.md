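# coldsplice

Quantification pipeline for cold-repressed poison-exon inclusion.

Mild hypothermia induces the cold-shock protein RBM3 in human neurons, and
the induction is controlled at the level of alternative splicing: RBM3
carries a *poison exon* (PE) — a cassette exon with in-frame premature
termination codons — whose inclusion routes the transcript into
nonsense-mediated decay (NMD). Cooling represses PE inclusion, and the
splicing factor HNRNPH1, binding a G-rich/G-quadruplex element in the PE,
promotes PE skipping. Establishing that mechanism takes a chain of small,
bespoke quantifications spread over very different assays. This package
implements each of them as tested, reusable code, together with a
synthetic-data generator so that every stage can be validated by parameter
recovery instead of downloads:

| stage | module | what it computes |
|---|---|---|
| gel PSI | `splice_psi` | length-normalized molar percent-spliced-in from band intensities |
| junction PSI | `splice_psi` | effective-length-normalized PSI from junction-spanning reads (SAM) |
| qPCR | `qpcr_rip` | ΔCt relative expression, relative PE inclusion, fold changes |
| RIP | `qpcr_rip` | input- and IP-efficiency-normalized binding fold change on cooling |
| FACS screen | `screen_counts` | exact 20-mer sgRNA counting, non-targeting-null gene enrichment |
| imaging | `imagequant` | nucleus/soma/cytoplasm segmentation and mean intensity per unit area |
| iCLIP / G4 | `clip_g4` | crosslinks-per-million tracks, rolling-mean smoothing, G4 motif scan |
| simulation | `synthetic_data` | ground-truth-labelled inputs for every stage above |

## The statistics at the core

**Gel PSI.** On an intercalating-dye gel, band intensity is proportional to
mass (mol × length), so dividing by fragment length recovers molar signal.
With inclusion bands *i* and one skipped band,

    PSI = Σᵢ (I_inc,i / L_inc,i) / ( Σᵢ (I_inc,i / L_inc,i) + I_skip / L_skip )

**Junction PSI.** For a cassette exon with inclusion-junction reads
I_up + I_down and skipping-junction reads S,

    PSI = ((I_up + I_down) / ℓ_inc) / ((I_up + I_down) / ℓ_inc + S / ℓ_skip)

with ℓ_inc = 2·ℓ, ℓ_skip = ℓ, and ℓ = read_length − 2·(min_anchor − 1) the
effective length of a single junction.

**NMD decay algebra.** If molecules include the PE with probability *p* at
synthesis and PE-included molecules survive NMD with probability ν, the
steady-state inclusion fraction is

    p′ = p·ν / (p·ν + 1 − p)

so blocking NMD (ν → 1) raises the apparent PE fraction — the
SMG1-inhibitor logic, reproduced by the simulator and the demo.

**RIP normalization.** The binding change on cooling divides out both the
input mRNA change and the pulldown efficiency change:

    FC = (IP₃₂/IP₃₇) ÷ (input₃₂/input₃₇) ÷ (eff₃₂/eff₃₇),  eff = IP protein / input protein

**Screen enrichment.** Reads are counted by exact 20-mer hash lookup
(anything without an exact library match is discarded). Per guide,
z = (LFC − median_NT)/MAD_NT against the non-targeting controls; per gene,
the mean guide z with a size-matched random-set permutation p-value and
Benjamini–Hochberg q across genes.

## Worked example

```bash
python analysis/01_simulate_cold_splice.py --seed 1
python analysis/02_psi_estimates.py --seed 1
```

simulates four paired 37 °C/32 °C replicates (10⁵ molecules each) from one
shared ground truth per replicate, then runs all three PSI estimators:

```
           psi_truth  psi_junction  psi_gel  psi_qpcr
condition
32C           0.0020        0.0020   0.0020    0.0020
37C           0.0234        0.0233   0.0234    0.0239
cooling effect on junction PSI: -0.0213 (permutation p = 0.042, 70 assignments)
```

All three assays agree with the molecular ground truth, and cooling
represses inclusion from PSI ≈ 0.023 to ≈ 0.002 — the warm/cold regime of
the long PE variant. The permutation p is the minimum attainable for 4+4
replicates under the (b+1)/(m+1) correction. The remaining drivers run the
screen (`03`, recovers all 10 spiked genes at q < 0.05), the imaging suite
(`04`, median compartment-mean error < 2 % at SNR 10) and the
crosslink-track/G4 scan (`05`).

The same stages are available from the shell, e.g.:

```bash
coldsplice demo --seed 1 --out demo/
coldsplice gel-psi --input bands=bands.csv --out out/
coldsplice screen count --input library=lib.tsv --input low=low.fastq \
    --input high=high.fastq --out counts/
```

## Layout

```
src/coldsplice/     library: one module per pipeline stage + pipeline/CLI
analysis/           numbered narrative drivers writing tables to results/
tests/              pytest suite (unit, property, end-to-end recovery)
scripts/            acceptance.py
docs/methods.md     models, assumptions, parameter choices, limitations
```
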