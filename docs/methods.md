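# Methods

This note documents the models behind each stage, the parameter choices
that matter, what the synthetic data does and does not emulate, and the
numerical conventions. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Splicing model and PSI estimators

A three-exon cassette event (upstream exon – poison exon – downstream
exon) is simulated at the molecule level: each molecule includes the PE
with probability `psi_true` at synthesis; PE-included molecules survive
nonsense-mediated decay with probability `nmd_survival`. The surviving
pool's inclusion fraction therefore converges to

    p' = p·ν / (p·ν + 1 − p),

which the simulator exposes both analytically (`post_decay_inclusion`) and
empirically (ground-truth counts). Published steady-state PSI values are
post-NMD quantities, so the cold-repression demo simulates the surviving
pool at those values directly (ν = 1) and a separate arm varies ν at fixed
synthesis-level inclusion to reproduce the NMD-inhibitor contrast.

Junction reads are sampled **position-uniformly**: an included molecule
exposes two junctions and a skipped molecule one, so a read is an
inclusion read with probability 2p′/(1+p′). This makes the
effective-length-normalized estimator

    PSI = (I/2ℓ) / (I/2ℓ + S/ℓ),  ℓ = read_length − 2·(min_anchor − 1)

consistent for p′. Reads are emitted one per surviving molecule (depth =
surviving pool size) with anchors ≥ `min_anchor` on both sides, so every
emitted read is countable at the default anchor setting.

Defaults: read length 100 nt; `min_anchor` 6 nt (a common junction-counting
anchor; the upstream tools' exact setting is not published, so the default
is declared, not inferred); exon/intron layout 150/300/100/300/150 nt —
intron-scale distances keep junction gaps unambiguous. Coordinates are
0-based half-open everywhere; a junction is the half-open gap (donor end,
acceptor start). Reads are counted once per junction; secondary and
supplementary records are ignored; strand filtering is opt-in (the RT-PCR
assays are unstranded).

Undefined PSI (no informative signal) is an explicit flagged state
(`PsiValue.defined = False`), never a silent zero.

`delta_psi` enumerates all C(n,k) label assignments when feasible
(otherwise samples), and applies the (b+1)/(m+1) correction in both modes;
with 2+2 replicates the minimum attainable two-sided p is therefore 3/7.

## Gel model

Band intensity = molar amount × fragment length × gain + truncated
Gaussian noise. Mass-proportional staining is the physical rationale for
the length division in the PSI formula: on noiseless bands the estimator
recovers the molar inclusion fraction exactly (the acceptance suite
measures the worst-case error over 1,000 random draws). Background
subtraction of real gel images is out of scope; band intensities are taken
as given in the input table.

## qPCR model

Ct = Ct_ref − log₂(expression) + noise per technical replicate, i.e.
amplification efficiency fixed at 2.0 (perfect doubling), configurable per
call. Technical replicates (default 4) are collapsed by arithmetic mean of
Ct before exponentiation; optional outlier dropping removes replicates
> 0.5 cycles from their replicate median (off by default). Relative PE
inclusion divides the PE amplicon's relative expression by a constitutive
amplicon or a mean of several; analyses of this assay vary in whether the
denominator is a single constitutive amplicon, the arithmetic mean, or the
geometric mean of several, so the mode is a required explicit parameter
(the geometric mode equals the geometric mean of the single-denominator
ratios). RIP fold
change divides out the input RNA change and the IP efficiency change, so
it is invariant to independent rescaling of RNA and protein units.

## Screen model

Guide counts are negative-binomial around library-proportional means
(variance μ + αμ², α = 0.1 by default; α = 0 gives Poisson) — counts from
pooled screens are overdispersed relative to Poisson, and the enrichment
statistic should be exercised under that overdispersion. Effect guides'
means are multiplied in the designated (low-GFP) pool. Reads are 21 nt,
single-end, with the exact 20-nt guide at offset 0 and a constant Q30
quality placeholder; a configurable fraction carries one random
substitution inside the 20-mer to exercise the discard rule. A mutated
20-mer could in principle collide with another library guide; at
20 nt over random libraries this is vanishingly rare and is ignored.

Counting is an exact hash lookup of the read's 20-mer (optional ±1-nt
offset scan, off by default); everything else is discarded and tallied, so
matched + discarded = total always. Scoring standardizes guide LFCs
against the non-targeting median/scaled-MAD (falling back to an all-guide
null below 10 controls), aggregates by mean z per gene, and draws
size-matched random guide sets for a one-sided permutation p (enrichment
in the low pool = candidate positive regulator), BH-corrected across
genes. This is deliberately not an RRA-style rank aggregation; the count
table exports in a MAGeCK-compatible layout for users who want that tool.

Acceptance-scale conditions: 210 genes × 4 guides + 100 non-targeting
controls at 3 × 10⁵ reads per pool (≈ 320× per-guide coverage) — a
scaled-down library at realistic coverage, with 10 genes spiked 8-fold.

## Image model and segmentation

Synthetic cells are one soma disk with a nucleus disk strictly inside it;
per channel each compartment has a true mean on top of a background level
(default 10) with an optional linear gradient (default up to 2) plus
Gaussian noise, clipped at zero like a real detector. The suite used by
the tests draws 100 random geometries with reporter SNR 10 (noise SD =
cytoplasm mean / 10).

Background removal subtracts the median of pixels outside a coarse
foreground mask (triangle threshold). When zero-clipped noise spikes the
histogram, the triangle threshold collapses and classifies nearly the
whole image as foreground; the mask then falls back to Otsu. Rolling-ball
removal is available as an alternative.

Nucleus: Otsu on the background-removed source channel (nuclear stain, or
the reporter where the reporter is predominantly nuclear), binary closing
(radius 2 px), largest connected component. Soma: Otsu scaled by a floor
factor (default 0.5) to keep the dim cytoplasmic rim, hole filling,
largest component, then union with the nucleus so nucleus ⊆ soma always
holds. Because Otsu always splits a histogram — even of pure noise — a
cell is only accepted if the foreground exceeds the background by at least
4 robust noise SDs (scaled MAD of the raw channel outside the mask);
otherwise the stage reports no cell. Cytoplasm = soma ∧ ¬nucleus, so the
three masks partition exactly by construction. Inputs are single-cell
crops; multi-cell fields keep the largest cell. Means are plain masked
means (total intensity / area) of whatever channel the caller passes —
background-correct first to match the reported quantities.

What the image simulator does not emulate: neurite morphology, 3-D
structure, uneven illumination beyond a linear gradient, and
photon-counting (Poisson) noise. Passing tests show the pipeline recovers
disk-geometry compartment means under Gaussian noise; they do not certify
performance on ramified neuronal morphologies.

## Crosslink tracks and G4 scanning

Tracks are strand-specific per-position counts over a 0-based half-open
window; normalization is counts × 10⁶ / library size (a per-library-
fraction convention would differ only by a global constant). Smoothing is
a centered rolling mean, window 5 by default, with the shrinking-window
convention at the edges (positions near an edge average over what exists);
a window longer than the vector yields the global mean everywhere. The
plotting tool that popularized this smoothing does not state its edge
convention, so this one is chosen and documented.

The G4 scanner enumerates every placement of four G-tracts of equal length
g ≥ `min_tract` (default 2) within `max_len` (default 30), loops 0–36.
The score is a documented QGRS-style variant:

    score = 100·g − 2·(max loop − min loop) − Σ loops

Tract length dominates (no loop geometry can outrank a longer-tract
candidate), then loop evenness, then compactness. Overlapping candidates
are resolved greedily to the highest-scoring non-overlapping set
(tie-breaks: shorter span, then leftmost). The contract is motif
presence/absence and tract structure — not any external tool's numeric
score, which this variant does not attempt to match. U is treated as T
and N breaks tracts, so RNA and masked sequences scan unchanged.

## Reproducibility and problem sizes

Every generator and every stochastic statistic takes an explicit seed; one
seeded generator per run drives all draws, and rerunning any stage with
the same config and seed is byte-identical (covered by tests). The
analysis drivers and the acceptance script use desk-scale problem sizes —
junction depth 10⁵ with 4 replicates per condition, the screen scale
above, 100 image geometries — chosen so the full pipeline re-runs
deterministically in seconds while keeping Monte-Carlo error well inside
each check's tolerance.

## Known limitations

- The junction counter requires exact donor/acceptor matches; it does not
  model soft-clipped or mismatched anchors, indels near junctions, or
  multi-mapping ambiguity.
- The screen statistic assumes guide independence within genes and a
  symmetric null; it is a plumbing statistic, not a calibrated replacement
  for rank-aggregation methods on real screens.
- qPCR efficiency is assumed equal across amplicons unless overridden; no
  standard-curve estimation is provided.
- The G4 scanner is sequence-only; it predicts motif candidates, not
  thermodynamic stability or temperature dependence.
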