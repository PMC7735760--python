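"""Synthetic fibre simulator with known nucleosome positions.

Generates molecules whose per-base IPD traces encode a configurable
nucleosome landscape: accessible linker adenines receive methylated (slow)
IPD draws, nucleosome-protected adenines unmethylated (fast) draws.  Two
pattern families are supported: *regular* arrays with a fixed nucleosome
repeat length (NRL), emulating tandem 601-positioned in vitro arrays, and
*irregular* fibres whose linker lengths are drawn from a broad geometric
sampler so that no dominant periodicity exists.  Every simulated molecule
comes with its ground truth (dyad positions and per-position methylation),
making the whole downstream pipeline testable without sequencing data.

IPD emission is log-normal on both branches.  Defaults place the methylated
log-mean 1.1 natural-log units above the unmethylated one (about a 3-fold
IPD increase) with sd 0.5 on both, overlapping enough that the two-component
mixture decoder is exercised rather than trivially separable.  The true
on-instrument fold-change of m6dA is not publicly calibrated; these defaults
are a tunable stand-in.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FeatureSet, Molecule

# Widom 601 core positioning sequence (147 bp), used for in vitro-style
# arrays so protected stretches carry the canonical sequence.
WIDOM_601 = (
    "CTGGAGAATCCCGGTGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTACG"
    "CGCTGTCCCCCGCGTTTTAACCGCCAAGGGGATTACTCCCTAGTCTCCAGGCACGTGTCAGATATATACAT"
    "CCTGT"
)


@dataclass
class FibreSpec:
    """Geometry and footprinting propensities of one simulated fibre pattern.

    ``linker_meth_prob`` / ``occluded_meth_prob`` are the per-adenine
    probabilities of methylation outside / inside a nucleosome footprint.
    ``dyad_jitter_sd`` jitters regular dyads around the arithmetic grid,
    clamped so adjacent dyads stay at least one footprint apart.
    """

    pattern_id: str
    pattern_type: str  # "regular" | "irregular"
    n_nucleosomes: int
    nrl: int | None = None
    footprint: int = 147
    dyad_jitter_sd: float = 2.0
    linker_meth_prob: float = 0.9
    occluded_meth_prob: float = 0.05
    flank5: int = 0
    flank3: int = 0
    seq_mode: str = "random"  # "random" | "array601"
    # irregular linker sampler: shifted geometric, 5 bp floor, 250 bp cap
    linker_mean: float = 40.0
    linker_floor: int = 5
    linker_max: int = 250

    def __post_init__(self) -> None:
        if self.pattern_type not in ("regular", "irregular"):
            raise ValueError(f"unknown pattern_type {self.pattern_type!r}")
        if self.n_nucleosomes < 1:
            raise ValueError("n_nucleosomes must be >= 1")
        if self.pattern_type == "regular":
            if self.nrl is None:
                raise ValueError("regular pattern requires nrl")
            if self.nrl <= self.footprint:
                raise ValueError(
                    f"nrl ({self.nrl}) must exceed footprint ({self.footprint})"
                )
        for name in ("linker_meth_prob", "occluded_meth_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.footprint < 1 or self.flank5 < 0 or self.flank3 < 0:
            raise ValueError("footprint must be positive, flanks non-negative")
        if self.linker_mean <= self.linker_floor:
            raise ValueError("linker_mean must exceed linker_floor")
        if self.seq_mode not in ("random", "array601"):
            raise ValueError(f"unknown seq_mode {self.seq_mode!r}")


@dataclass
class IPDModel:
    """Log-normal IPD emission for unmethylated vs methylated positions."""

    unmeth_logmean: float = 0.0
    unmeth_logsd: float = 0.5
    meth_logmean: float = 1.1
    meth_logsd: float = 0.5
    context_effect_sd: float = 0.0
    missing_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.meth_logmean <= self.unmeth_logmean:
            raise ValueError("meth_logmean must exceed unmeth_logmean")
        if self.unmeth_logsd <= 0 or self.meth_logsd <= 0:
            raise ValueError("log-sds must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.context_effect_sd < 0:
            raise ValueError("context_effect_sd must be >= 0")


@dataclass
class SimTruth:
    """Ground truth for one simulated molecule."""

    molecule_id: str
    pattern_id: str
    true_dyads: np.ndarray
    fragment_interval: tuple[int, int]
    meth_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.true_dyads = np.asarray(self.true_dyads, dtype=int)
        if np.any(np.diff(self.true_dyads) <= 0):
            raise ValueError("dyads must be strictly increasing")


def draw_linkers(spec: FibreSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Irregular linker lengths: ``floor`` + shifted geometric, capped.

    The geometric component has mean ``linker_mean - linker_floor`` so the
    uncapped linker mean equals ``linker_mean`` (40 bp by default), giving a
    broad spread of spacings with no dominant periodicity.
    """
    p = 1.0 / (spec.linker_mean - spec.linker_floor + 1.0)
    raw = spec.linker_floor + rng.geometric(p, size=n) - 1
    return np.minimum(raw, spec.linker_max)


def plan_nucleosomes(spec: FibreSpec, seed: int) -> np.ndarray:
    """Place ``n_nucleosomes`` dyads on a molecule, reproducibly under seed.

    Regular: dyads sit at ``flank5 + footprint//2 + k*nrl`` plus Gaussian
    jitter, sequentially clamped so adjacent dyads stay >= footprint apart.
    Irregular: sequential placement with linkers from :func:`draw_linkers`.
    """
    rng = np.random.default_rng(seed)
    half = spec.footprint // 2
    if spec.pattern_type == "regular":
        base = spec.flank5 + half + np.arange(spec.n_nucleosomes) * spec.nrl
        if spec.dyad_jitter_sd > 0:
            base = base + rng.normal(0.0, spec.dyad_jitter_sd, spec.n_nucleosomes)
        dyads = np.rint(base).astype(int)
        dyads[0] = max(dyads[0], half)
        for i in range(1, len(dyads)):
            dyads[i] = max(dyads[i], dyads[i - 1] + spec.footprint)
    else:
        linkers = draw_linkers(spec, spec.n_nucleosomes - 1, rng)
        dyads = np.empty(spec.n_nucleosomes, dtype=int)
        dyads[0] = spec.flank5 + half
        for i in range(1, spec.n_nucleosomes):
            dyads[i] = dyads[i - 1] + spec.footprint + linkers[i - 1]
    return dyads


def molecule_length(spec: FibreSpec, dyads: np.ndarray) -> int:
    return int(dyads[-1]) + (spec.footprint - spec.footprint // 2) + spec.flank3


def _context_offset(kmer: str, sd: float, salt: int) -> float:
    """Deterministic zero-mean per-k-mer offset (stable across processes)."""
    h = hashlib.blake2b(f"{salt}:{kmer}".encode(), digest_size=8).digest()
    sub = np.random.default_rng(int.from_bytes(h, "little"))
    return float(sub.normal(0.0, sd))


def emit_molecule(
    dyads: np.ndarray,
    spec: FibreSpec,
    ipd_model: IPDModel,
    seed: int,
    molecule_id: str = "mol0",
    context_salt: int = 0,
) -> tuple[Molecule, SimTruth]:
    """Generate the base string and IPD trace for one planned molecule.

    Each A/T position is methylated with probability ``linker_meth_prob``
    outside every footprint interval ``[dyad - footprint//2,
    dyad + footprint//2]`` and ``occluded_meth_prob`` inside; IPDs are drawn
    from the corresponding log-normal.  G/C positions always draw from the
    unmethylated branch (adenine methyltransferases leave them untouched,
    which is what makes them a usable per-molecule speed anchor downstream).
    A ``missing_rate`` fraction of A/T observations is masked.
    """
    dyads = np.asarray(dyads, dtype=int)
    half = spec.footprint // 2
    L = molecule_length(spec, dyads)
    rng = np.random.default_rng(seed)

    base_arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=L)
    if spec.seq_mode == "array601":
        core = np.frombuffer(WIDOM_601.encode(), dtype=np.uint8)
        for d in dyads:
            lo = max(d - half, 0)
            hi = min(d - half + len(core), L)
            base_arr[lo:hi] = core[lo - (d - half) : hi - (d - half)]
    bases = base_arr.tobytes().decode("ascii")

    at = (base_arr == ord("A")) | (base_arr == ord("T"))
    protected = np.zeros(L, dtype=bool)
    for d in dyads:
        protected[max(d - half, 0) : min(d + half + 1, L)] = True

    meth_p = np.where(protected, spec.occluded_meth_prob, spec.linker_meth_prob)
    meth = at & (rng.random(L) < meth_p)

    logmean = np.where(meth, ipd_model.meth_logmean, ipd_model.unmeth_logmean)
    logsd = np.where(meth, ipd_model.meth_logsd, ipd_model.unmeth_logsd)
    if ipd_model.context_effect_sd > 0:
        n5, n3 = 2, 5
        offs = np.zeros(L)
        for i in np.nonzero(at)[0]:
            if i - n5 < 0 or i + n3 >= L:
                continue
            kmer = bases[i - n5 : i + n3 + 1]
            offs[i] = _context_offset(kmer, ipd_model.context_effect_sd, context_salt)
        logmean = logmean + offs
    ipd = np.exp(rng.normal(logmean, logsd))

    if ipd_model.missing_rate > 0:
        drop = at & (rng.random(L) < ipd_model.missing_rate)
        ipd[drop] = np.nan

    mol = Molecule(
        molecule_id=molecule_id,
        ref_name=molecule_id,
        ref_start=0,
        ref_end=L,
        strand="+",
        bases=bases,
        ipd=ipd,
    )
    truth = SimTruth(
        molecule_id=molecule_id,
        pattern_id=spec.pattern_id,
        true_dyads=dyads,
        fragment_interval=(0, L),
        meth_mask=meth,
    )
    return mol, truth


def simulate_sample(
    mixture: Sequence[tuple[FibreSpec, float]],
    n_molecules: int,
    ipd_model: IPDModel,
    seed: int,
    id_prefix: str = "mol",
) -> tuple[list[Molecule], list[SimTruth], pd.DataFrame]:
    """Draw a mixture of fibre patterns: multinomial pattern counts under seed.

    Returns molecules, per-molecule truth, and a two-column label table
    (molecule_id, pattern_id).  Identical seeds give byte-identical output.
    """
    if not mixture:
        raise ValueError("mixture must not be empty")
    weights = np.array([w for _, w in mixture], dtype=float)
    if weights.min() < 0 or abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("mixture weights must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_molecules, weights)
    pattern_of = rng.permutation(np.repeat(np.arange(len(mixture)), counts))
    child_seeds = rng.integers(0, 2**31 - 1, size=(n_molecules, 2))

    width = max(4, len(str(n_molecules)))
    molecules: list[Molecule] = []
    truths: list[SimTruth] = []
    labels = []
    for i in range(n_molecules):
        spec = mixture[pattern_of[i]][0]
        mol_id = f"{id_prefix}{i:0{width}d}"
        dyads = plan_nucleosomes(spec, int(child_seeds[i, 0]))
        mol, truth = emit_molecule(
            dyads, spec, ipd_model, int(child_seeds[i, 1]),
            molecule_id=mol_id, context_salt=seed,
        )
        molecules.append(mol)
        truths.append(truth)
        labels.append((mol_id, spec.pattern_id))
    label_df = pd.DataFrame(labels, columns=["molecule_id", "pattern_id"])
    return molecules, truths, label_df


def simulate_mnase_fragments(
    dyads: np.ndarray,
    spec: FibreSpec,
    cut_jitter_sd: float,
    seed: int,
    cut_prob: float = 0.5,
) -> list[tuple[int, int]]:
    """Nuclease fragmentation of one fibre: cuts land in linkers only.

    Each internal linker midpoint is cut with probability ``cut_prob``; cut
    positions get Gaussian jitter and are clamped into the linker interior,
    so no cut can fall inside a nucleosome footprint.  The molecule ends are
    always cut.  For regular fibres the resulting fragment lengths
    concentrate near integer multiples of the NRL.
    """
    dyads = np.asarray(dyads, dtype=int)
    if dyads.size < 1:
        raise ValueError("need at least one nucleosome")
    rng = np.random.default_rng(seed)
    half = spec.footprint // 2
    L = molecule_length(spec, dyads)

    cuts = [0]
    for d0, d1 in zip(dyads[:-1], dyads[1:]):
        if rng.random() >= cut_prob:
            continue
        lo = d0 + half + 1  # first base past the upstream footprint
        hi = d1 - half - 1  # last base before the downstream footprint
        if lo > hi:
            continue  # abutting nucleosomes: no linker to cut
        mid = (d0 + d1) / 2.0
        c = int(np.floor(mid + rng.normal(0.0, cut_jitter_sd) + 0.5))
        cuts.append(int(np.clip(c, lo, hi)))
    cuts.append(L)
    cuts = sorted(set(cuts))
    return [(a, b) for a, b in zip(cuts[:-1], cuts[1:])]


def truth_features(truths: Sequence[SimTruth]) -> FeatureSet:
    """Truth dyads as 1-bp BED intervals with chrom = molecule_id."""
    rows = []
    for t in truths:
        for d in t.true_dyads:
            rows.append((t.molecule_id, int(d), int(d) + 1, t.pattern_id, 0, "+"))
    return FeatureSet(pd.DataFrame(rows, columns=FeatureSet.COLUMNS))


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
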