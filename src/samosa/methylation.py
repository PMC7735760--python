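"""From raw IPDs to per-molecule methylation posteriors.

The decoder has three steps:

1. **Per-molecule normalization.** IPDs are transformed as ``log2(IPD)``
   and robust-z-scored (median / scaled MAD) within each molecule.  The
   anchor statistics are computed over the molecule's observed G/C
   positions by default: G/C template bases can never carry m6dA, so they
   pin the molecule's baseline polymerase speed even when every adenine is
   methylated (a median over positions that include the methylated adenines
   themselves recentres heavily methylated molecules toward zero and makes
   them indistinguishable from unmethylated controls).  Any constant
   A/T-versus-G/C kinetic offset is absorbed into the fitted component
   means, since the mixture is learned on the anchored values.  ``"all"``
   and ``"at"`` anchors are available for data where the G/C baseline is
   unusable.  Non-positive IPDs are treated as missing.
2. **A two-component Gaussian mixture** fit by EM on normalized values
   pooled across the sample (optionally per molecule).  Component 1 is the
   slow (methylated) component, enforced by relabeling so ``mu1 > mu0``.
3. **Posterior decoding**: each observed A/T position receives
   ``P(methylated | z)`` under the fitted mixture.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .io import ModificationTrack, Molecule

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma under normality


@dataclass
class MixtureModel:
    """Two-component 1-D Gaussian mixture on the normalized log-IPD scale."""

    w1: float
    mu0: float
    mu1: float
    sd0: float
    sd1: float

    @property
    def w0(self) -> float:
        return 1.0 - self.w1

    def __post_init__(self) -> None:
        if not 0.0 <= self.w1 <= 1.0:
            raise ValueError("w1 must be in [0, 1]")
        if self.sd0 <= 0 or self.sd1 <= 0:
            raise ValueError("component sds must be positive")
        if self.mu1 <= self.mu0:
            raise ValueError("component 1 must be the slow (higher-mean) component")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"w1": self.w1, "mu0": self.mu0, "mu1": self.mu1,
                 "sd0": self.sd0, "sd1": self.sd1},
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "MixtureModel":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class NormalizedTrack:
    """Normalized log-IPD per base; NaN outside observed A/T positions."""

    molecule_id: str
    z: np.ndarray
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class MixtureFit:
    """EM result: the model plus the log-likelihood trajectory and flags."""

    model: MixtureModel
    loglik: np.ndarray
    converged: bool
    n_used: int
    flags: tuple[str, ...] = ()


def normalize_ipd(
    m: Molecule,
    min_at: int = 20,
    anchor: str = "gc",
    min_anchor: int = 10,
) -> NormalizedTrack:
    """Robust per-molecule z of ``log2(IPD)``.

    ``anchor`` chooses which observed positions supply the median/MAD:
    ``"gc"`` (default: the never-methylated internal reference), ``"all"``
    or ``"at"``.  A G/C anchor with fewer than ``min_anchor`` observations
    falls back to all observed positions.  Molecules with fewer than
    ``min_at`` observed A/T positions, or with zero spread after the sd
    fallback, are flagged and should be excluded downstream.
    """
    if anchor not in ("gc", "all", "at"):
        raise ValueError(f"unknown anchor {anchor!r}")
    at = m.at_mask
    obs = np.isfinite(m.ipd) & (m.ipd > 0)
    scored = at & obs
    z = np.full(len(m), np.nan)
    if scored.sum() < min_at:
        return NormalizedTrack(m.molecule_id, z, True, "low_information")

    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(obs, np.log2(np.where(obs, m.ipd, 1.0)), np.nan)
    if anchor == "gc":
        ref = ~at & obs
        if ref.sum() < min_anchor:
            ref = obs
    elif anchor == "all":
        ref = obs
    else:
        ref = scored
    med = np.median(x[ref])
    mad = np.median(np.abs(x[ref] - med))
    scale = MAD_SCALE * mad
    if scale == 0.0:
        scale = float(np.std(x[ref]))  # fallback for quantized/degenerate IPDs
        if scale == 0.0:
            return NormalizedTrack(m.molecule_id, z, True, "zero_spread")
        logger.warning(
            "molecule %s: MAD is zero, falling back to sd", m.molecule_id
        )
    z[scored] = (x[scored] - med) / scale
    return NormalizedTrack(m.molecule_id, z)


def pooled_z(
    molecules: Iterable[Molecule],
    min_at: int = 20,
    anchor: str = "gc",
) -> tuple[np.ndarray, list[str]]:
    """Concatenate finite normalized values across molecules for a sample fit."""
    chunks = []
    flagged = []
    for m in molecules:
        t = normalize_ipd(m, min_at=min_at, anchor=anchor)
        if t.flagged:
            flagged.append(m.molecule_id)
            continue
        chunks.append(t.z[np.isfinite(t.z)])
    if flagged:
        logger.info("%d molecules flagged during normalization", len(flagged))
    if not chunks:
        return np.empty(0), flagged
    return np.concatenate(chunks), flagged


def fit_mixture(
    z: np.ndarray,
    max_iter: int = 2000,
    tol: float = 1e-4,
    seed: int = 0,
    var_floor: float = 1e-3,
    min_weight: float = 0.02,
    min_n: int = 1000,
    max_points: int = 200_000,
) -> MixtureFit:
    """EM fit of the two-component mixture on pooled normalized values.

    Initialization is deterministic under ``seed``: component means start at
    the 25th/75th percentiles, equal weights, a shared sd; the seed only
    matters when ``z`` is subsampled to ``max_points``.  The log-likelihood
    is recorded each iteration and is non-decreasing up to round-off; a
    variance floor and a minimum-weight flag guard the usual EM
    degeneracies.  ``max_iter=0`` returns the initialization unchanged.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < min_n:
        raise ValueError(f"need >= {min_n} finite values to fit, got {z.size}")
    rng = np.random.default_rng(seed)
    if z.size > max_points:
        z = rng.choice(z, size=max_points, replace=False)

    q25, q75 = np.quantile(z, [0.25, 0.75])
    if q75 - q25 < 1e-6:
        q25, q75 = q25 - 0.5, q75 + 0.5
    sd_init = max(float(np.std(z)) / 2.0, float(np.sqrt(var_floor)))
    w = np.array([0.5, 0.5])
    mu = np.array([q25, q75])
    sg = np.array([sd_init, sd_init])

    flags: list[str] = []
    loglik: list[float] = []
    converged = False
    log_2pi = np.log(2.0 * np.pi)
    for _ in range(max_iter):
        # inline normal log-densities: the EM loop dominates fit cost
        zc = (z[None, :] - mu[:, None]) / sg[:, None]
        logp = (
            np.log(w)[:, None]
            - 0.5 * zc * zc
            - np.log(sg)[:, None]
            - 0.5 * log_2pi
        )
        tot = logsumexp(logp, axis=0)
        ll = float(tot.sum())
        if loglik and ll < loglik[-1] - 1e-8 * max(1.0, abs(loglik[-1])):
            flags.append("nonmonotone")
        if loglik and abs(ll - loglik[-1]) < tol:
            loglik.append(ll)
            converged = True
            break
        loglik.append(ll)

        r = np.exp(logp - tot[None, :])
        nk = r.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        w = nk / z.size
        mu = (r @ z) / nk
        var = (r @ (z * z)) / nk - mu**2
        if np.any(var < var_floor):
            flags.append("var_floor")
            logger.warning("variance floor %g applied during EM", var_floor)
        sg = np.sqrt(np.maximum(var, var_floor))

    if mu[0] > mu[1]:  # relabel: component 1 is the methylated (slow) one
        w, mu, sg = w[::-1].copy(), mu[::-1].copy(), sg[::-1].copy()
    if min(w) < min_weight:
        flags.append("min_weight")
        logger.warning(
            "mixture weight %.4f below %.2f: sample may be single-component",
            min(w), min_weight,
        )
    model = MixtureModel(w1=float(w[1]), mu0=float(mu[0]), mu1=float(mu[1]),
                         sd0=float(sg[0]), sd1=float(sg[1]))
    return MixtureFit(
        model=model,
        loglik=np.asarray(loglik),
        converged=converged,
        n_used=int(z.size),
        flags=tuple(dict.fromkeys(flags)),
    )


def posterior(model: MixtureModel, z: np.ndarray | float) -> np.ndarray:
    """``P(methylated | z)`` under the mixture; NaN propagates."""
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    out = np.full(z.shape, np.nan)
    fin = np.isfinite(z)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        l0 = np.log(model.w0) + norm.logpdf(z[fin], model.mu0, model.sd0)
        l1 = np.log(model.w1) + norm.logpdf(z[fin], model.mu1, model.sd1)
        d = l0 - l1
        p = 1.0 / (1.0 + np.exp(d))
    bad = ~np.isfinite(p)
    if np.any(bad):  # both densities underflowed: nearest-mean rule
        zn = z[fin][bad]
        p[bad] = (np.abs(zn - model.mu1) < np.abs(zn - model.mu0)).astype(float)
        logger.warning("posterior underflow at %d positions, nearest-mean used",
                       int(bad.sum()))
    out[fin] = p
    return float(out[0]) if scalar else out


def call_sample(
    molecules: Sequence[Molecule],
    model: MixtureModel | None,
    per_molecule: bool = False,
    min_at: int = 20,
    anchor: str = "gc",
    score: str = "AT",
    **fit_kwargs,
) -> tuple[list[ModificationTrack], list[str]]:
    """Posterior track per molecule; flagged molecules are returned separately.

    With ``per_molecule=True`` a fresh mixture is fit inside every molecule
    (``model`` then serves as a fallback for molecules too small to fit).
    ``score="T"`` restricts calls to thymine template positions.
    """
    if score not in ("AT", "T"):
        raise ValueError(f"unknown score mode {score!r}")
    tracks: list[ModificationTrack] = []
    flagged: list[str] = []
    for m in molecules:
        t = normalize_ipd(m, min_at=min_at, anchor=anchor)
        if t.flagged:
            flagged.append(m.molecule_id)
            continue
        mol_model = model
        if per_molecule:
            zfin = t.z[np.isfinite(t.z)]
            try:
                mol_model = fit_mixture(
                    zfin, min_n=min(200, max(50, len(zfin))), **fit_kwargs
                ).model
            except ValueError:
                if model is None:
                    flagged.append(m.molecule_id)
                    continue
        if mol_model is None:
            raise ValueError("call_sample needs a fitted model (or per_molecule)")
        prob = posterior(mol_model, t.z)
        if score == "T":
            prob = np.where(m.base_codes == ord("T"), prob, np.nan)
        tracks.append(ModificationTrack(m.molecule_id, prob))
    return tracks, flagged


def context_profile(
    molecules: Sequence[Molecule],
    n5: int = 2,
    n3: int = 5,
    min_at: int = 20,
    anchor: str = "gc",
    hist_bins: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequence-context summary of normalized IPDs.

    Bins every observed A/T position by its (n5 + 1 + n3)-mer context
    (``n5`` bases 5' and ``n3`` bases 3' of the template base); windows
    truncated by molecule ends are skipped.  Returns a per-context table
    (count, mean z) sorted by mean normalized IPD, plus a per-context
    histogram of z values.
    """
    if hist_bins is None:
        hist_bins = np.linspace(-5.0, 5.0, 41)
    ctx_all: list[str] = []
    z_all: list[np.ndarray] = []
    w = n5 + 1 + n3
    for m in molecules:
        t = normalize_ipd(m, min_at=min_at, anchor=anchor)
        if t.flagged:
            continue
        pos = np.nonzero(np.isfinite(t.z))[0]
        pos = pos[(pos >= n5) & (pos + n3 < len(m))]
        if pos.size == 0:
            continue
        if w == 1:
            ctx_all.extend(m.bases[i] for i in pos)
        else:
            ctx_all.extend(m.bases[i - n5 : i + n3 + 1] for i in pos)
        z_all.append(t.z[pos])
    if not z_all:
        empty = pd.DataFrame(columns=["context", "count", "mean_z"])
        return empty, pd.DataFrame()
    df = pd.DataFrame({"context": ctx_all, "z": np.concatenate(z_all)})
    summary = (
        df.groupby("context")["z"]
        .agg(count="count", mean_z="mean")
        .reset_index()
        .sort_values("mean_z", kind="mergesort")
        .reset_index(drop=True)
    )
    hists = df.groupby("context")["z"].apply(
        lambda v: pd.Series(np.histogram(v, bins=hist_bins)[0])
    ).unstack(fill_value=0)
    hists = hists.loc[summary["context"]]
    return summary, hists
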