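# Methods

This package analyses single-molecule adenine-methyltransferase
footprinting data read out through real-time sequencing kinetics, and
ships a simulator that generates such data with known ground truth. This
note documents the models, the defaults and why they were chosen, and what
the simulation-based tests do and do not demonstrate.

## Signal model

In a footprinting experiment an exogenous, nonspecific adenine
methyltransferase (e.g. EcoGII) deposits m6dA on accessible (linker) DNA;
nucleosome-protected stretches stay unmethylated. During single-molecule
real-time sequencing the polymerase pauses at methylated template
adenines, raising the interpulse duration (IPD) at those bases. A molecule
is therefore a base string with a per-base IPD vector, missing where no
kinetic observation was made; all per-molecule vectors are kept in read
orientation and converted to reference orientation only at export or
overlap time.

## Methylation calling

1. **Normalization.** Per molecule, `z = (log2(IPD) − median) / (1.4826 ·
   MAD)`, with the median/MAD taken over the molecule's observed **G/C**
   positions. G/C template bases cannot carry m6dA, so they anchor the
   molecule's baseline polymerase speed regardless of how methylated the
   molecule is; an anchor that includes adenines (options `"all"`, `"at"`
   are provided) recentres fully methylated molecules toward z ≈ 0 and
   destroys the separation between methylated and unmethylated controls.
   A constant A/T-versus-G/C kinetic offset in real data is harmless: the
   mixture below is fit on the anchored values, so the offset is absorbed
   into the component means. Non-positive IPDs are treated as missing;
   molecules with fewer than 20 observed A/T positions, or with zero
   kinetic spread, are flagged and excluded.
2. **Mixture.** A two-component Gaussian mixture is fit by EM on the
   normalized values pooled across the sample (per-molecule fitting is
   available behind a flag; the pooled fit is the default because a single
   molecule rarely carries enough adenines to constrain four shape
   parameters). Initialization is deterministic: means at the 25th/75th
   percentiles, equal weights, a shared sd. Components are relabelled so
   component 1 is the slow (methylated) one. Guard rails: a variance floor
   of 1e-3, a minimum-weight flag at 0.02 (fires on effectively
   single-component samples), a recorded log-likelihood trajectory that
   must be non-decreasing, convergence at |Δ log-likelihood| < 1e-4 with
   up to 2000 iterations (overlapping components converge slowly; a few
   hundred iterations are typical), and subsampling to 200 000 points for
   speed (seeded, hence reproducible).
3. **Posterior.** Each observed A/T position receives
   `P(methylated | z) = w1·φ(z; μ1, σ1) / Σ w_k·φ(z; μ_k, σ_k)`, computed
   in log space; if both densities underflow the call falls back to the
   nearest-mean rule. Both A and T template positions are scored by
   default (consensus reads interleave both strands' adenine signal);
   `score="T"` restricts to thymines.

## Nucleosome footprints

* **Smoothing.** Posterior tracks are smoothed with a centred NaN-aware
  rolling mean: 5 bp for defined in vitro arrays, 33 bp for genomic
  fibres (wide enough to bridge local A/T deserts).
* **Dyad calling** (arrays): local minima of a 133-bp rolling mean,
  accepted greedily from the deepest up subject to a 147-bp minimum
  separation, ties leftmost; positions without a full smoothing window
  and minima within 73 bp (half a footprint) of either end are excluded.
  Two additions beyond the minimal recipe, both fixed before the
  benchmarks were frozen: minima must lie in the lower 60% of the
  smoothed track's range (a dip that stays near the methylated level is
  accessible DNA, not a nucleosome — without this the ~450 bp
  nucleosome-free end of the array template sheds spurious calls), and
  each accepted minimum is refined to the weighted centroid of its trough
  (bottom 25% of the local range within ±40 bp, symmetrized at truncated
  edges). Both rules are invariant to adding a constant to the track, and
  both leave noiseless geometry unchanged (a flat-bottomed trough's
  centroid is its midpoint).
* **NRL from dyads**: pairwise adjacent-dyad distances, and the
  single-molecule average `(last − first)/(n − 1)`.
* **Autocorrelograms**: at lag k, the Pearson correlation between
  `track[0:L−k)` and `track[k:L)` over positions observed in both copies.
  Lags where the windows would be shorter than half the molecule are not
  computed, so the autocorrelogram has exactly `⌊L/2⌋` entries; lags with
  fewer than 10 overlapping observations are missing rather than
  extrapolated. A fully observed track takes an FFT path; any missing
  value falls back to an exact masked loop (both verified against an
  O(L²) oracle to 1e-10).
* **NRL peak calling**: the first autocorrelogram peak in lag range
  [120, 350] bp with prominence ≥ 0.03 and correlation ≥ 0.1. The
  prominence/height pair was tuned once on simulated averages so that
  regular fibres in the 170–200 bp range are called robustly; molecules
  with no qualifying peak are recorded as `peak_found=False`, never
  dropped — missing peaks concentrate in irregular fibres and are
  themselves a readout of regularity.

## Fibre clustering

Molecules ≥ 500 bp get autocorrelograms computed on their 5′ ≤ 1000 bp;
rows are truncated to the 250 lags every eligible molecule shares
(avoiding padding artifacts from ragged lengths), residual missing lags
are imputed with the row mean, and a Euclidean 15-nearest-neighbour graph
is clustered with Leiden under the modularity objective (seeded,
clusters relabelled by descending size, clusters under 100 molecules
flagged rather than merged). Resolution is a genuine knob: modularity on
kNN graphs fragments homogeneous data at resolution ≥ 0.5, so the
planted-pattern recovery tests run at resolution 0.1–0.3, chosen by the
criterion of avoiding many small clusters, not by the recovery score.
Cluster summaries report size fractions, per-cluster single-molecule NRL
median/MAD, the missing-peak fraction, and mean modification and
autocorrelation profiles.

## Feature-centric analyses

Molecules are assigned to features when their alignment interval overlaps
the feature expanded by 1 kb, boundary included. Motif windows are the
500 bp centred on the motif midpoint (`⌊(start+end)/2⌋`), reference
oriented, minus-strand motifs mirrored; molecules lacking 250 bp of flank
on either side are excluded and counted. Nuclease-cut profiles accumulate
both fragment ends of every overlapping molecule at their (strand-
flipped) offset from the motif midpoint, normalized per contributing
molecule. Accessibility states at motifs are clustered with the same
Leiden machinery on 33-bp-smoothed window rows.

Enrichment of clusters within molecule categories uses Fisher's exact
test on 2×2 tables against the background of all labelled molecules
(molecules carrying several category labels count once per category —
deduplicating across categories would silently discard multi-domain
molecules), followed by Storey q-values across the whole scan with
significance at q < 0.1. π0 is estimated on the λ grid 0.05…0.95 with a
cubic smoothing spline evaluated at λ = 0.95, clipped to (0, 1]; with
fewer than 20 p-values π0 is fixed at 1, reducing the procedure exactly
to Benjamini–Hochberg. GC-matched control regions are sampled without
replacement bin-for-bin (2.5% GC bins) from a candidate universe;
repeat-content matching is deliberately out of scope — externally built
control BEDs can be supplied where it matters.

## The simulator and what the tests show

The simulator emits molecules from *fibre specs*: regular arrays (dyads
on an `nrl` grid with Gaussian jitter, clamped to keep adjacent dyads a
footprint apart) or irregular fibres (linkers = 5 bp floor + geometric
with 40 bp mean, capped at 250 bp — broad spacing with no dominant
periodicity). Methylation is Bernoulli per adenine: 0.9 in linkers, 0.05
under footprints (enzyme efficiency and occasional breathing), and 10% of
A/T observations are masked as missing. IPDs are log-normal with
log-means 0 (unmethylated) and 1.1 (methylated) and sd 0.5 — roughly a
3-fold IPD increase, overlapping enough that posterior decoding is a real
inference problem; the true on-instrument fold-change of m6dA is not
publicly calibrated, so this is a stated stand-in, not a measured value.
Dyad jitter defaults to 2 bp (strong positioning sequences). An optional
zero-mean per-8-mer log-IPD offset exercises the sequence-context
profiler. Nuclease fragmentation cuts each linker midpoint with
probability 0.5 plus Gaussian jitter clamped into the linker, so cuts can
never fall inside a footprint and regular fibres produce the familiar
oligonucleosome ladder.

Benchmarks recomputed by `scripts/acceptance.py` at these defaults: on
1000 simulated nonanucleosomal 193-bp-repeat arrays the full pipeline
recovers a median pairwise adjacent-dyad distance of 193 bp and a median
|called − true| dyad deviation of ~2–3 bp; on 1000 regular NRL-172
fibres, autocorrelogram peak calling recovers a median single-molecule
NRL within 1 bp of 172. Problem sizes (1000 molecules per benchmark,
150–2400 for the other test fixtures) were chosen as comfortable desk
scale; medians are stable well below these sizes.

What the simulation does **not** emulate: sequence-dependent polymerase
kinetics beyond the optional k-mer offset, pass-count-dependent
consensus accuracy, enzyme processivity or concentration gradients along
fibres, mappability, and real genomic sequence composition. Passing
recovery tests therefore demonstrates that the estimators invert the
generative model they target — not that real libraries meet that model.
Two consequences observed in simulation are worth flagging: at the
default IPD overlap even a perfectly specified decoder leaves a fully
methylated control at a mean posterior near 0.7 (not ~1), and irregular
single fibres still carry genuine self-spacing correlation, so their
missing-peak excess over regular fibres is modest compared to what real,
noisier data shows.

## Numerical and degenerate-input choices

Zero-MAD molecules fall back to the standard deviation, then to a flag.
Fisher's p uses the conditional two-sided probability-mass rule (verified
by exhaustive enumeration for all tables with N ≤ 40); an empty margin
gives p = 1 with an undefined odds ratio, and the sample odds ratio
`ad/bc` is reported as infinite when `bc = 0, ad > 0`. Rolling means at
track ends are means over the truncated window (dyad calling masks those
positions instead). Dyad ties are broken leftmost. All randomness flows
through explicit integer seeds; identical seeds give byte-identical
outputs end to end, including the pipeline manifest digests.

## Known limitations

Per-molecule mixture fitting is provided but weakly constrained on short
molecules; the pooled fit assumes one global methylation chemistry per
sample. G/C anchoring assumes the G/C IPD spread is comparable to the
unmethylated A/T spread (exact in simulation, approximate on instruments).
Control matching ignores repeat content. The clustering representation
truncates information beyond the 5′ 1000 bp of long fibres.
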