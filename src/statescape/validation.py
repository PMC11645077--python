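"""End-to-end validation studies of the analysis pipeline.

These routines exercise the full chain on synthetic cohorts whose ground
truth is known — parameter recovery, energy/probability consistency,
landscape structure against exhaustive search, familywise error control of
the per-state tests and of the SPC permutation inference, and power to
recover a planted coupling difference — and recompute the demographic
summary-statistic tests of the reference cohort from its printed group
summaries.  Problem sizes default to the study-scale conditions the
synthetic generator emulates.
"""

from __future__ import annotations

import numpy as np

from .connectivity import connectivity_matrix, spc_cluster_inference
from .groups import bonferroni, build_profiles, energy_ttest_per_state, paired_state_frequencies
from .ising import boltzmann_distribution, energies, fit_mem, sample_ising
from .landscape import basin_assignment, local_minima
from .signals import empirical_distribution
from .simulate import CohortConfig, default_cohort_config, generate_cohort, planted_cohort_config
from .stats import GroupSummary, chi2_2x2, pooled_t, welch_t

__all__ = [
    "demographic_checks",
    "mem_recovery",
    "rank_inversion_agreement",
    "landscape_oracle_agreement",
    "state_test_fwer",
    "spc_null_fwe_rate",
    "spc_planted_detection",
    "planted_effect_study",
]

# Printed demographic/clinical group summaries of the two-group reference
# cohort (63 controls vs 55 patients) that the synthetic generator emulates;
# these published summary statistics are the *inputs* to the test routines.
DEMOGRAPHICS = {
    "age": ("pooled", GroupSummary(36.75, 13.62, 63, 34.53, 13.13, 55)),
    "auditory_state": ("welch", GroupSummary(0.08, 0.22, 63, 0.72, 0.94, 55)),
    "auditory_trait": ("welch", GroupSummary(0.42, 0.48, 63, 1.44, 1.23, 55)),
    "processing_speed": ("welch", GroupSummary(76.54, 14.07, 63, 62.37, 20.51, 55)),
}
SEX_TABLE = (42, 21, 38, 17)  # male/female counts per group


def demographic_checks() -> dict[str, float]:
    """Recompute the group comparisons from the printed summaries."""
    out = {}
    for name, (kind, summary) in DEMOGRAPHICS.items():
        res = pooled_t(summary) if kind == "pooled" else welch_t(summary)
        out[f"{name}_t"] = res.statistic
    out["sex_chi2"] = chi2_2x2(*SEX_TABLE).statistic
    return out


def _reference_params(n_rois: int, rng):
    h = rng.normal(0, 0.4, n_rois)
    upper = np.triu(rng.normal(0, 0.3, (n_rois, n_rois)), 1)
    from .ising import MEMParameters

    return MEMParameters(h=h, J=upper + upper.T)


def mem_recovery(n_rois: int = 8, n_samples: int = 50_000, seed: int = 0) -> dict:
    """Sample a known model and refit: correlation of true vs fitted (h, J)."""
    rng = np.random.default_rng(seed)
    truth = _reference_params(n_rois, rng)
    seq = sample_ising(truth, n_samples, seed=rng, method="exact")
    fitted, diag = fit_mem(empirical_distribution(seq), tol=1e-6)
    iu = np.triu_indices(n_rois, 1)
    true_vec = np.concatenate([truth.h, truth.J[iu]])
    fit_vec = np.concatenate([fitted.h, fitted.J[iu]])
    r = float(np.corrcoef(true_vec, fit_vec)[0, 1])
    return {"correlation": r, "converged": diag.converged, "n_samples": n_samples}


def exact_recovery_error(seed: int = 0) -> float:
    """Max parameter error after fitting an exactly enumerated N=3 model."""
    rng = np.random.default_rng(seed)
    truth = _reference_params(3, rng)
    fitted, _ = fit_mem(boltzmann_distribution(truth), tol=1e-10)
    return float(max(np.abs(fitted.h - truth.h).max(), np.abs(fitted.J - truth.J).max()))


def rank_inversion_agreement(n_models: int = 20, n_rois: int = 5,
                             n_samples: int = 888, seed: int = 0) -> float:
    """Fraction of fitted models whose probability order exactly reverses
    their energy order (the energy-probability inverse law)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_models):
        truth = _reference_params(n_rois, rng)
        seq = sample_ising(truth, n_samples, seed=rng)
        fitted, _ = fit_mem(empirical_distribution(seq), tol=1e-6)
        e = energies(fitted)
        p = boltzmann_distribution(fitted).probs
        agree += np.array_equal(np.argsort(p), np.argsort(-e))
    return agree / n_models


# -- exhaustive landscape reference ----------------------------------------


def _brute_minima(e):
    n = int(len(e)).bit_length() - 1
    return [k for k in range(len(e))
            if all(e[k] < e[k ^ (1 << i)] for i in range(n))]


def _brute_descent(e, k):
    n = int(len(e)).bit_length() - 1
    while True:
        best = min((k ^ (1 << i) for i in range(n)), key=lambda x: (e[x], x))
        if e[best] < e[k]:
            k = best
        else:
            return k


def _brute_saddle_depths(e, minima):
    size = len(e)
    n = int(size).bit_length() - 1
    mm = np.full((size, size), np.inf)
    for k in range(size):
        mm[k, k] = e[k]
        for i in range(n):
            j = k ^ (1 << i)
            mm[k, j] = max(e[k], e[j])
    for w in range(size):
        mm = np.minimum(mm, np.maximum(mm[:, [w]], mm[[w], :]))
    return {m: min(mm[m, o] for o in minima if o != m) - e[m] for m in minima}


def landscape_oracle_agreement(n_instances: int = 100, seed: int = 0) -> float:
    """Fraction of random small landscapes (N <= 4) on which minima, basins
    and depths all match exhaustive brute-force search."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_instances):
        n = int(rng.integers(2, 5))
        e = rng.normal(size=1 << n)
        summary = basin_assignment(e)
        ok = summary.minima == _brute_minima(e)
        ok &= all(summary.basin_of[k] == _brute_descent(e, k) for k in range(1 << n))
        if len(summary.minima) >= 2:
            brute = _brute_saddle_depths(e, summary.minima)
            ok &= all(abs(summary.depth[m] - brute[m]) < 1e-9 for m in summary.minima)
        else:
            m = summary.minima[0]
            ok &= abs(summary.depth[m] - (e.max() - e[m])) < 1e-12
        hits += ok
    return hits / n_instances


# -- error control ----------------------------------------------------------


def state_test_fwer(n_cohorts: int = 200, n_rois: int = 4, seed: int = 0,
                    alpha: float = 0.05, fit_tol: float = 1e-6) -> dict:
    """Familywise error of Bonferroni-corrected per-state energy tests on
    null cohorts (identical group-level parameters, study-size groups)."""
    false_alarms = 0
    for rep in range(n_cohorts):
        cfg = default_cohort_config(n_rois=n_rois)
        profiles = build_profiles(generate_cohort(cfg, seed=seed * n_cohorts + rep),
                                  tol=fit_tol)
        table = energy_ttest_per_state(profiles)
        _, sig = bonferroni(table["p"].to_numpy(), alpha=alpha)
        false_alarms += bool(np.nansum(sig))
    return {"fwer": false_alarms / n_cohorts, "n_cohorts": n_cohorts}


def _null_connectivity_dataset(rng, n_per_group, n_rois, T):
    mats, groups = [], []
    for i in range(2 * n_per_group):
        mats.append(connectivity_matrix(rng.normal(size=(T, n_rois))))
        groups.append("control" if i < n_per_group else "patient")
    return mats, groups


def spc_null_fwe_rate(n_datasets: int = 100, n_per_group: int = 20, n_rois: int = 8,
                      T: int = 200, n_perm: int = 500, seed: int = 0,
                      alpha: float = 0.05) -> dict:
    """Rate at which null data yields any cluster with FWE p below alpha."""
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(n_datasets):
        mats, groups = _null_connectivity_dataset(rng, n_per_group, n_rois, T)
        res = spc_cluster_inference(mats, groups, n_perm=n_perm, seed=rng.integers(2**31))
        p_min = min((c["p_FWE"] for c in res.clusters), default=1.0)
        hits += p_min < alpha
    return {"fwe_rate": hits / n_datasets, "n_datasets": n_datasets}


def spc_planted_detection(n_per_group: int = 30, n_rois: int = 8, T: int = 300,
                          shift: float = -0.8, n_perm: int = 1000, seed: int = 0) -> dict:
    """SPC on a dataset where one three-ROI block loses shared signal in the
    patient group; reports the top cluster's mass and FWE p-value."""
    rng = np.random.default_rng(seed)
    mats, groups = [], []
    for i in range(2 * n_per_group):
        g = "control" if i < n_per_group else "patient"
        x = rng.normal(size=(T, n_rois))
        common = rng.normal(size=T)
        w = 1.0 + (shift if g == "patient" else 0.0)
        for r in (0, 1, 2):
            x[:, r] += w * common
        mats.append(connectivity_matrix(x))
        groups.append(g)
    res = spc_cluster_inference(mats, groups, n_perm=n_perm, seed=seed)
    if not res.clusters:
        return {"n_clusters": 0, "min_p_fwe": 1.0, "top_mass": 0.0}
    top = res.clusters[0]
    return {"n_clusters": len(res.clusters), "min_p_fwe": top["p_FWE"],
            "top_mass": top["mass"], "top_size": top["size"]}


# -- planted-effect power ----------------------------------------------------


def affected_states(config: CohortConfig, top_k: int = 2) -> list[int]:
    """States whose model probability differs most between the two groups'
    ground-truth parameter sets (enumerated, no sampling)."""
    from .ising import MEMParameters

    p_ctrl = boltzmann_distribution(MEMParameters(config.base_h, config.base_J)).probs
    p_pat = boltzmann_distribution(
        MEMParameters(config.base_h + config.patient_delta_h,
                      config.base_J + config.patient_delta_J)).probs
    return np.argsort(np.abs(p_ctrl - p_pat))[::-1][:top_k].tolist()


def planted_effect_study(n_replicates: int = 50, delta: float = 0.6, seed: int = 0,
                         alpha: float = 0.05, fit_tol: float = 1e-6) -> dict:
    """Power to flag the planted-coupling states, and the direction of the
    paired-state frequency contrast (control-analogue minus patient-analogue).
    """
    cfg = planted_cohort_config(delta=delta)
    targets = affected_states(cfg, top_k=2)
    pair = tuple(sorted(targets))
    flagged = 0
    freq_diffs = []
    for rep in range(n_replicates):
        cohort = generate_cohort(cfg, seed=seed * n_replicates + rep)
        profiles = build_profiles(cohort, tol=fit_tol)
        table = energy_ttest_per_state(profiles).set_index("state")
        _, sig = bonferroni(table["p"].to_numpy(), alpha=alpha)
        sig_states = set(table.index[np.asarray(sig, dtype=bool)])
        flagged += set(targets) <= sig_states
        freqs = paired_state_frequencies(profiles, [pair])
        col = freqs.columns[1]
        means = freqs.groupby("group")[col].mean()
        freq_diffs.append(float(means["control"] - means["patient"]))
    freq_diffs = np.asarray(freq_diffs)
    return {
        "detection_rate": flagged / n_replicates,
        "mean_freq_control_minus_patient": float(freq_diffs.mean()),
        "direction_rate": float((freq_diffs > 0).mean()),
        "targets": targets,
        "n_replicates": n_replicates,
    }
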