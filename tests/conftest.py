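"""Shared fixtures: simulated datasets reused across test modules.

The expensive fixtures are session-scoped; every one is fully seeded so the
suite is deterministic run to run.
"""

from __future__ import annotations

import numpy as np
import pytest

from samosa import cluster as cl
from samosa import footprint as fp
from samosa import methylation as me
from samosa.sim import FibreSpec, IPDModel, simulate_sample


def run_calling(molecules, fit_seed=0):
    """Sample-level mixture fit + posterior tracks for a molecule list."""
    z, flagged = me.pooled_z(molecules)
    fit = me.fit_mixture(z, seed=fit_seed)
    tracks, flagged2 = me.call_sample(molecules, fit.model)
    return fit, tracks


@pytest.fixture(scope="session")
def array601():
    """1000 nonanucleosomal 601-style arrays with full dyad-calling output.

    The in vitro benchmark geometry: nine nucleosomes on a 193-bp repeat,
    ~450 bp of nucleosome-free DNA at the 3' end, default IPD noise.
    """
    spec = FibreSpec(
        "a601", "regular", 9, nrl=193, flank3=450, seq_mode="array601"
    )
    molecules, truths, labels = simulate_sample([(spec, 1.0)], 1000, IPDModel(), 1)
    fit, tracks = run_calling(molecules, fit_seed=1)
    callsets = []
    for t in tracks:
        sm = fp.rolling_mean_nan(t.prob, fp.IN_VITRO_SMOOTH)
        callsets.append(fp.call_dyads(sm, molecule_id=t.molecule_id))
    truth_by_id = {t.molecule_id: t for t in truths}
    return {
        "spec": spec,
        "molecules": molecules,
        "truths": truth_by_id,
        "fit": fit,
        "tracks": tracks,
        "callsets": callsets,
    }


@pytest.fixture(scope="session")
def fibres172():
    """1000 regular NRL-172 fibres with autocorrelogram NRL calls."""
    spec = FibreSpec("n172", "regular", 8, nrl=172, flank5=25, flank3=25)
    molecules, truths, labels = simulate_sample([(spec, 1.0)], 1000, IPDModel(), 2)
    fit, tracks = run_calling(molecules, fit_seed=2)
    calls = []
    for t in tracks:
        sm = fp.rolling_mean_nan(t.prob, fp.IN_VIVO_SMOOTH)
        acg = fp.autocorrelogram(sm, molecule_id=t.molecule_id)
        calls.append(fp.find_nrl_peak(acg))
    return {"molecules": molecules, "tracks": tracks, "nrl_calls": calls}


@pytest.fixture(scope="session")
def planted_mix():
    """Four planted patterns (irregular + NRL 172/187/193), 2400 fibres.

    Provides the fibre matrix and per-molecule truth labels for clustering
    recovery tests, plus NRL peak calls for summaries.
    """
    specs = [
        FibreSpec("irs", "irregular", 8, flank5=25, flank3=25),
        FibreSpec("n172", "regular", 8, nrl=172, flank5=25, flank3=25),
        FibreSpec("n187", "regular", 8, nrl=187, flank5=25, flank3=25),
        FibreSpec("n193", "regular", 8, nrl=193, flank5=25, flank3=25),
    ]
    molecules, truths, labels = simulate_sample(
        [(s, 0.25) for s in specs], 2400, IPDModel(), 12
    )
    fit, tracks = run_calling(molecules, fit_seed=3)
    acgs, _ = cl.autocorrelogram_matrix(tracks)
    matrix = cl.build_matrix(acgs)
    calls = []
    for t in tracks:
        sm = fp.rolling_mean_nan(t.prob, fp.IN_VIVO_SMOOTH)
        try:
            acg = fp.autocorrelogram(sm, molecule_id=t.molecule_id)
        except ValueError:
            continue
        calls.append(fp.find_nrl_peak(acg))
    truth_map = dict(zip(labels["molecule_id"], labels["pattern_id"]))
    return {
        "molecules": molecules,
        "tracks": tracks,
        "matrix": matrix,
        "truth_map": truth_map,
        "nrl_calls": calls,
    }


@pytest.fixture(scope="session")
def control_trio():
    """Chromatin, fully methylated and unmethylated samples, 150 fibres each.

    The mixture model is fit on the chromatin sample only and applied to
    all three, as in a footprinting experiment with naked-DNA controls.
    """
    base = dict(nrl=193, flank5=25, flank3=25)
    chrom_spec = FibreSpec("chrom", "regular", 8, **base)
    meth_spec = FibreSpec(
        "meth", "regular", 8, linker_meth_prob=1.0, occluded_meth_prob=1.0, **base
    )
    un_spec = FibreSpec(
        "unmeth", "regular", 8, linker_meth_prob=0.0, occluded_meth_prob=0.0, **base
    )
    ipd = IPDModel()
    chrom, chrom_truth, _ = simulate_sample(
        [(chrom_spec, 1.0)], 150, ipd, 21, id_prefix="chrom"
    )
    methylated, _, _ = simulate_sample(
        [(meth_spec, 1.0)], 150, ipd, 22, id_prefix="meth"
    )
    unmethylated, _, _ = simulate_sample(
        [(un_spec, 1.0)], 150, ipd, 23, id_prefix="un"
    )
    z, _ = me.pooled_z(chrom)
    fit = me.fit_mixture(z, seed=0)
    tracks = {
        name: me.call_sample(mols, fit.model)[0]
        for name, mols in (
            ("chrom", chrom), ("meth", methylated), ("unmeth", unmethylated)
        )
    }
    return {
        "fit": fit,
        "tracks": tracks,
        "chrom_molecules": chrom,
        "chrom_truths": chrom_truth,
    }
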