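"""End-to-end validation studies on synthetic cohorts with known truth.

These routines define the package's canonical self-checks at a desk-scale
problem size: DTF normalization on random stable models, convergence of the
estimated DTF to the analytic DTF of the generating coefficients, type-I
calibration of the surrogate threshold on channel-independent noise, and
full-pipeline recovery of injected band-power and coupling effects.  They
are used by the test suite and by the reproduction script.

Problem sizes are the package's demo scale: recovery cohorts use 20
subjects per group, 20-s recordings at 125 Hz (4 five-second epochs) and
100 surrogates; calibration uses 8 channels with 200 surrogates.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from .connectivity import (MVARModel, cohort_connectivity_table, dtf,
                           fit_mvar, frequency_grid, observed_dtf_mean,
                           simulate_mvar, surrogate_threshold,
                           threshold_network, transfer_function)
from .spectral import Band, cohort_band_table
from .stats import compare_groups
from .report import summarize_edges
from .synthetic import BandEffect, CohortSpec, Coupling, generate_cohorts

__all__ = [
    "random_stable_mvar",
    "dtf_rowsum_max_deviation",
    "dtf_oracle_errors",
    "surrogate_type1",
    "recovery_study",
]

ALPHA_BAND = Band("alpha", 8.0, 13.0)


def random_stable_mvar(
    k: int, p: int, rng: np.random.Generator, radius: float = 0.9
) -> List[np.ndarray]:
    """Random MVAR(p) coefficients rescaled to companion spectral radius
    below ``radius``."""
    coeffs = [rng.normal(0.0, 0.3 / np.sqrt(k), (k, k)) for _ in range(p)]
    for _ in range(100):
        m = MVARModel(order=p, coeffs=coeffs, resid_cov=np.eye(k), n_samples_used=1)
        r = m.companion_spectral_radius()
        if r < radius:
            return coeffs
        coeffs = [a * 0.8 for a in coeffs]
    raise RuntimeError("could not stabilize random MVAR")


def dtf_rowsum_max_deviation(seed: int, n_models: int = 100, k: int = 5) -> float:
    """Max |sum_j gamma2[i,j](f) - 1| over random stable MVAR(2) models."""
    rng = np.random.default_rng(seed)
    freqs = frequency_grid()
    worst = 0.0
    for _ in range(n_models):
        coeffs = random_stable_mvar(k, 2, rng)
        m = MVARModel(order=2, coeffs=coeffs, resid_cov=np.eye(k), n_samples_used=1)
        g = dtf(transfer_function(m, freqs, 250.0))
        worst = max(worst, float(np.abs(g.sum(axis=-1) - 1.0).max()))
    return worst


def dtf_oracle_errors(seed: int, n_samples: int = 5000) -> Dict[str, float]:
    """Estimated vs analytic DTF for a fixed lower-triangular 2-channel
    MVAR(1) (channel 1 drives channel 2, no reverse)."""
    A = np.array([[0.5, 0.0], [0.4, 0.5]])
    freqs = frequency_grid()
    truth = MVARModel(order=1, coeffs=[A], resid_cov=np.eye(2), n_samples_used=1)
    g_true = dtf(transfer_function(truth, freqs, 250.0))
    X = simulate_mvar([A], n_samples, np.random.default_rng(seed))
    g_est = dtf(transfer_function(fit_mvar(X, 1), freqs, 250.0))
    return {
        "max_abs_error": float(np.abs(g_est - g_true).max()),
        "reverse_edge_max": float(g_est[:, 0, 1].max()),
        "n_samples": n_samples,
    }


def surrogate_type1(
    seed: int,
    k: int = 8,
    n_datasets: int = 5,
    n_epochs: int = 12,
    epoch_samples: int = 1250,
    sample_rate: float = 250.0,
    n_surrogates: int = 200,
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Fraction of directed edges surviving the surrogate threshold on
    channel-independent white noise, pooled over independent datasets."""
    rng = np.random.default_rng(seed)
    count, total = 0, 0
    for _ in range(n_datasets):
        eps = rng.standard_normal((n_epochs, k, epoch_samples))
        null = surrogate_threshold(
            eps, [ALPHA_BAND], order=2, n_surrogates=n_surrogates,
            alpha=alpha, rng=rng, sample_rate=sample_rate,
        )
        obs = observed_dtf_mean(eps, [ALPHA_BAND], order=2, sample_rate=sample_rate)
        net = threshold_network(obs["alpha"], null.thresholds["alpha"])
        count += int((net > 0).sum())
        total += k * (k - 1)
    return {"count": count, "n_edges": total, "fraction": count / total}


def _recovery_spec(seed: int) -> CohortSpec:
    """Study conditions for the recovery runs: delta boost at Fz/CP1 in the
    impaired group and one directed coupling PO3 -> CP5."""
    return CohortSpec(
        n_subjects_per_group=20,
        duration_s=20.0,
        sample_rate_hz=125.0,
        band_effects=[BandEffect("MCI", "delta", ("Fz", "CP1"), 1.5)],
        couplings=[Coupling("MCI", "PO3", "CP5", "alpha", 0.4, 2)],
        seed=seed,
    )


def recovery_run(seed: int, n_surrogates: int = 100) -> Dict[str, bool]:
    """One seeded end-to-end run; reports which ground-truth facts the
    pipeline recovered after FDR."""
    recs, _ = generate_cohorts(_recovery_spec(seed))
    band_table = cohort_band_table(recs)
    el_cmp = compare_groups(band_table)
    sig_delta = el_cmp[
        (el_cmp.band == "delta") & el_cmp.significant & (el_cmp.direction == "MCI>NC")
    ]
    delta_ok = {"Fz", "CP1"} <= set(sig_delta.electrode)

    conn = cohort_connectivity_table(
        recs, bands=(ALPHA_BAND,), order=2,
        n_surrogates=n_surrogates, alpha=0.05, seed=seed + 1,
    )
    edge_cmp = compare_groups(conn, value_col="value",
                              unit_cols=["source", "target"])
    findings = summarize_edges(edge_cmp)
    fwd = findings[(findings.source == "PO3") & (findings.target == "CP5")]
    edge_ok = (
        len(fwd) == 1
        and fwd.iloc[0].orientation == "bottom-up"
        and fwd.iloc[0].direction == "MCI>NC"
    )
    rev = edge_cmp[(edge_cmp.source == "CP5") & (edge_cmp.target == "PO3")]
    reverse_ok = not bool(rev.iloc[0].significant)
    return {
        "delta_ok": delta_ok,
        "edge_ok": edge_ok,
        "reverse_ok": reverse_ok,
        "success": delta_ok and edge_ok and reverse_ok,
    }


def recovery_study(seed: int, n_runs: int = 20,
                   n_surrogates: int = 100) -> Dict[str, object]:
    """Repeat :func:`recovery_run` over independently seeded cohorts."""
    run_seeds = (np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)).tolist()
    runs = [recovery_run(int(s), n_surrogates=n_surrogates) for s in run_seeds]
    return {
        "runs": runs,
        "n_runs": n_runs,
        "success_fraction": sum(r["success"] for r in runs) / n_runs,
        "delta_fraction": sum(r["delta_ok"] for r in runs) / n_runs,
        "edge_fraction": sum(r["edge_ok"] for r in runs) / n_runs,
        "reverse_significant_fraction":
            sum(not r["reverse_ok"] for r in runs) / n_runs,
    }
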