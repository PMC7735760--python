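"""Feature-centric analyses and enrichment statistics.

Molecules are assigned to genomic features (motif sites, chromatin-domain
intervals) by interval overlap with a 1-kb expansion, posterior signal is
extracted in strand-aware 500-bp windows centred on motif midpoints,
nuclease-cut profiles are accumulated from fragment ends, and cluster-by-
category contingency tables are tested with Fisher's exact test followed by
Storey q-value correction (significance at q < 0.1).  Control regions are
drawn GC-matched from a candidate universe; externally supplied control
BEDs can be used instead when repeat-content matching is required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.stats import fisher_exact

from .cluster import ClusterAssignment, leiden_cluster
from .footprint import rolling_mean_nan
from .io import FeatureSet, ModificationTrack, Molecule

logger = logging.getLogger(__name__)


@dataclass
class MotifWindowMatrix:
    """Posterior windows centred on motif (or control) midpoints.

    Rows are in reference orientation with minus-strand motifs flipped, so
    column 0 is always the motif's 5' side; ``categories`` carries the motif
    (or control-set) name per row.
    """

    molecule_ids: list[str]
    matrix: np.ndarray  # n x (2 * flank)
    categories: list[str]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("window matrix must be 2-D")
        if self.matrix.shape[0] != len(self.molecule_ids) or self.matrix.shape[
            0
        ] != len(self.categories):
            raise ValueError("row annotations do not match matrix")


@dataclass
class ContingencyTable:
    a: int  # in cluster and in category
    b: int  # in cluster, not in category
    c: int  # not in cluster, in category
    d: int  # neither

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def assign_molecules(
    molecules: Sequence[Molecule],
    features: FeatureSet,
    max_dist: int = 1000,
) -> pd.DataFrame:
    """Molecule-to-feature hits: overlap within ``max_dist`` (boundary closed).

    A molecule hits a feature when its alignment interval overlaps the
    feature interval expanded by ``max_dist`` on both sides, the expansion
    boundary included (a gap of exactly ``max_dist`` is a hit).  Molecules
    may hit several features; all hits are kept, with the alignment start/
    end relative to the feature start and the molecule strand recorded.
    """
    mol_chroms = {m.ref_name for m in molecules}
    skipped = set(features.df["chrom"]) - mol_chroms
    if skipped:
        logger.warning("features on %d contigs without molecules skipped",
                       len(skipped))
    by_chrom: dict[str, list[Molecule]] = {}
    for m in molecules:
        by_chrom.setdefault(m.ref_name, []).append(m)

    rows = []
    for fi, f in enumerate(features):
        for m in by_chrom.get(f.chrom, ()):
            if m.ref_end >= f.start - max_dist and m.ref_start <= f.end + max_dist:
                rows.append(
                    {
                        "molecule_id": m.molecule_id,
                        "feature_index": fi,
                        "feature_name": f.name,
                        "rel_start": m.ref_start - f.start,
                        "rel_end": m.ref_end - f.start,
                        "strand": m.strand,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["molecule_id", "feature_index", "feature_name",
                 "rel_start", "rel_end", "strand"],
    )


def motif_windows(
    molecules: Sequence[Molecule],
    tracks: Mapping[str, ModificationTrack] | Sequence[ModificationTrack],
    motifs: FeatureSet,
    flank: int = 250,
) -> MotifWindowMatrix:
    """Posterior signal in ``[mid - flank, mid + flank)`` around each motif.

    The motif midpoint is ``(start + end) // 2``.  Tracks are converted to
    reference orientation (reversed for minus-strand molecules), the window
    is extracted, and rows from minus-strand motifs are mirrored so all rows
    read 5'->3' across the motif.  Molecules not fully covering the window
    are excluded and counted.
    """
    if not isinstance(tracks, Mapping):
        tracks = {t.molecule_id: t for t in tracks}
    by_chrom: dict[str, list[Molecule]] = {}
    for m in molecules:
        by_chrom.setdefault(m.ref_name, []).append(m)

    ids: list[str] = []
    rows: list[np.ndarray] = []
    cats: list[str] = []
    excluded = 0
    for f in motifs:
        mid = (f.start + f.end) // 2
        lo, hi = mid - flank, mid + flank
        for m in by_chrom.get(f.chrom, ()):
            t = tracks.get(m.molecule_id)
            if t is None:
                continue
            if m.ref_start > lo or m.ref_end < hi:
                excluded += 1
                continue
            ref_vals = t.prob if m.strand == "+" else t.prob[::-1]
            row = ref_vals[lo - m.ref_start : hi - m.ref_start].copy()
            if f.strand == "-":
                row = row[::-1]
            ids.append(m.molecule_id)
            rows.append(row)
            cats.append(f.name)
    if not rows:
        logger.warning("no molecule fully covers any motif window")
        return MotifWindowMatrix([], np.empty((0, 2 * flank)), [], excluded)
    return MotifWindowMatrix(ids, np.vstack(rows), cats, excluded)


def cut_profile(
    molecules: Sequence[Molecule],
    motifs: FeatureSet,
    halfwidth: int = 1000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fragment-end (nuclease cut) counts around motif midpoints.

    Both ends of every molecule overlapping ``[mid - halfwidth,
    mid + halfwidth]`` contribute one count at their offset from the motif
    midpoint, sign-flipped for minus-strand motifs.  Returns
    ``(offsets, per-molecule-normalized counts, n_molecule_hits)``.
    """
    offsets = np.arange(-halfwidth, halfwidth + 1)
    counts = np.zeros(offsets.size)
    by_chrom: dict[str, list[Molecule]] = {}
    for m in molecules:
        by_chrom.setdefault(m.ref_name, []).append(m)
    n_hits = 0
    for f in motifs:
        mid = (f.start + f.end) // 2
        for m in by_chrom.get(f.chrom, ()):
            if m.ref_end < mid - halfwidth or m.ref_start > mid + halfwidth:
                continue
            n_hits += 1
            for end in (m.ref_start, m.ref_end):
                off = end - mid
                if f.strand == "-":
                    off = -off
                if -halfwidth <= off <= halfwidth:
                    counts[off + halfwidth] += 1
    profile = counts / n_hits if n_hits else counts
    return offsets, profile, n_hits


def state_cluster(
    windows: MotifWindowMatrix,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    smooth_window: int = 33,
) -> tuple[ClusterAssignment, np.ndarray]:
    """Leiden clustering of motif-window posterior rows (33-bp smoothed).

    Returns the assignment plus per-cluster mean window profiles; rows whose
    smoothed window is entirely missing are imputed at 0.5 (uninformative).
    """
    if windows.matrix.shape[0] < 50:
        raise ValueError("need at least 50 window rows to cluster states")
    sm = np.vstack([rolling_mean_nan(r, smooth_window) for r in windows.matrix])
    for row in sm:
        miss = ~np.isfinite(row)
        if miss.any():
            row[miss] = row[~miss].mean() if (~miss).any() else 0.5
    assignment = leiden_cluster(
        sm, k_neighbors=k_neighbors, resolution=resolution, seed=seed,
        molecule_ids=windows.molecule_ids,
    )
    ncl = assignment.n_clusters
    profiles = np.vstack(
        [sm[assignment.labels == c].mean(axis=0) for c in range(ncl)]
    )
    return assignment, profiles


def fisher_test(t: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns the sample odds ratio ``a*d / (b*c)`` (infinite when ``b*c = 0``
    with ``a*d > 0``) and the conditional p-value summing hypergeometric
    probabilities no larger than the observed table's.  An empty margin
    yields p = 1 with an undefined (NaN) odds ratio.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a + b, c + d, a + c, b + d) == 0:
        return np.nan, 1.0
    if b * c == 0:
        oddsratio = np.inf if a * d > 0 else np.nan
    else:
        oddsratio = (a * d) / (b * c)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return oddsratio, float(min(p, 1.0))


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Smoother estimate of the null proportion pi0.

    ``pi0(lambda) = mean(p > lambda) / (1 - lambda)`` on the lambda grid,
    smoothed with a cubic spline and evaluated at the largest lambda,
    clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    spline = UnivariateSpline(lambdas, pi0_l, k=3)
    return float(np.clip(spline(lambdas[-1]), 1e-8, 1.0))


def storey_qvalues(
    p_values: np.ndarray,
    pi0: float | None = None,
    lambdas: np.ndarray | None = None,
) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 (the null proportion) is estimated on the lambda grid 0.05..0.95
    from the tail counts ``mean(p > lambda) / (1 - lambda)``, smoothed with
    a cubic spline and read off at the largest lambda, clipped to (0, 1].
    With fewer than 20 p-values pi0 is fixed at 1, reducing the procedure to
    Benjamini-Hochberg; ``pi0`` may also be forced explicitly.  Output is in
    [0, 1] and monotone non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 20:
            logger.info("fewer than 20 p-values: pi0 fixed at 1 (BH)")
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(p, lambdas)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # q_i = min over p_j >= p_i
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def interval_gc(seq: str) -> float:
    """GC fraction over unambiguous bases; NaN when none."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return np.nan
    return (s.count("G") + s.count("C")) / acgt


def matched_controls(
    candidate_universe: FeatureSet,
    targets: FeatureSet,
    genome_seq: Mapping[str, str],
    bin_width: float = 0.025,
    seed: int = 0,
) -> FeatureSet:
    """GC-binned matched control sampling without replacement.

    Candidates are sampled bin-for-bin to reproduce the target GC histogram
    (bins of ``bin_width``, 2.5% by default).  Under-populated bins borrow
    from the nearest neighbouring bins, with a logged warning.  Repeat
    content is not matched; supply externally built control BEDs when that
    matters.
    """
    rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(1.0 / bin_width))

    def _bins(fs: FeatureSet) -> np.ndarray:
        gc = np.array(
            [interval_gc(str(genome_seq[f.chrom])[f.start : f.end]) for f in fs]
        )
        return np.minimum((gc / bin_width).astype(int), n_bins - 1)

    tbins = _bins(targets)
    cbins = _bins(candidate_universe)
    pool = {b: list(np.nonzero(cbins == b)[0]) for b in range(n_bins)}
    for b in pool:
        rng.shuffle(pool[b])

    chosen: list[int] = []
    for b, need in zip(*np.unique(tbins, return_counts=True)):
        take = pool[b][:need]
        pool[b] = pool[b][len(take):]
        short = need - len(take)
        if short > 0:
            logger.warning(
                "GC bin %d under-populated by %d: borrowing from neighbours",
                b, short,
            )
            for dist in range(1, n_bins):
                for nb in (b - dist, b + dist):
                    if short == 0 or not 0 <= nb < n_bins:
                        continue
                    extra = pool[nb][:short]
                    pool[nb] = pool[nb][len(extra):]
                    take.extend(extra)
                    short -= len(extra)
                if short == 0:
                    break
        chosen.extend(take)
    df = candidate_universe.df.iloc[sorted(chosen)].reset_index(drop=True)
    return FeatureSet(df)


def enrichment_scan(
    assignment: ClusterAssignment,
    categories: pd.DataFrame | Mapping[str, Sequence[str]],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """One Fisher test per (cluster, category) against all labelled molecules.

    ``categories`` maps molecules to zero or more category labels (a
    DataFrame with ``molecule_id``/``category`` columns or a mapping).  The
    background is the set of all labelled molecules within the assignment; a
    molecule carrying several labels counts once per category.  q-values are
    computed across the whole scan, significance flagged at q < ``fdr``.
    """
    if isinstance(categories, Mapping):
        cat_df = pd.DataFrame(
            [(mid, c) for mid, cs in categories.items() for c in cs],
            columns=["molecule_id", "category"],
        )
    else:
        cat_df = categories[["molecule_id", "category"]].copy()
    cat_df = cat_df.drop_duplicates()

    cluster_of = dict(zip(assignment.molecule_ids, assignment.labels))
    cat_df = cat_df[cat_df["molecule_id"].isin(cluster_of)]
    labelled = set(cat_df["molecule_id"])
    n_total = len(labelled)
    if n_total == 0:
        return pd.DataFrame(
            columns=["cluster", "category", "a", "b", "c", "d",
                     "odds_ratio", "p_value", "q_value", "significant"]
        )
    cluster_members: dict[int, set] = {}
    for mid in labelled:
        cluster_members.setdefault(cluster_of[mid], set()).add(mid)
    cat_members = {
        c: set(sub["molecule_id"]) for c, sub in cat_df.groupby("category")
    }

    rows = []
    for cl in sorted(cluster_members):
        in_cl = cluster_members[cl]
        for cat in sorted(cat_members):
            in_cat = cat_members[cat]
            a = len(in_cl & in_cat)
            b = len(in_cl) - a
            c = len(in_cat) - a
            d = n_total - a - b - c
            oddsratio, p = fisher_test(ContingencyTable(a, b, c, d))
            rows.append(
                {"cluster": cl, "category": cat, "a": a, "b": b, "c": c,
                 "d": d, "odds_ratio": oddsratio, "p_value": p}
            )
    table = pd.DataFrame(rows)
    table["q_value"] = storey_qvalues(table["p_value"].to_numpy())
    table["significant"] = table["q_value"] < fdr
    return table
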