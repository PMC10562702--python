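"""Weighted co-expression networks per wave and transcriptomal hub calling.

Within each expression wave, an unsigned weighted adjacency
``a_ij = |cor(x_i, x_j)|**beta`` is built over the members' time-point mean
profiles; the soft power ``beta`` is the smallest one whose connectivity
distribution fits a scale-free topology (signed R^2 of log10 p(k) vs
log10 k at or above a threshold).  A gene's whole-network connectivity is
``k_i = sum_{j != i} a_ij`` and hubs are the top decile of connectivity
within the wave (count = ceil(0.10 * wave size), ties broken by feature
identifier order).  Hub sets can then be intersected across genotypes,
overall and per age phase, and transcription-factor hubs flagged as
transcriptionally regulated from a genotype-contrast table.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_POWERS = tuple(range(1, 21))
DEFAULT_FIT_THRESHOLD = 0.80
HUB_FRACTION = 0.10
UNSIGNED_DEFAULT_POWER = 6   # conventional soft power for unsigned networks

#: Age phases of the six time points (months).
PHASE_MAP: dict[float, str] = {
    0.6: "very early", 1.0: "early", 2.5: "middle", 4.0: "middle",
    6.0: "late", 12.0: "late",
}


def _flat_profiles(x: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Rows without real temporal variance, with a tolerance for the
    ulp-level jitter left by averaging identical replicates."""
    return x.std(axis=1) <= rtol * (1.0 + np.abs(x.mean(axis=1)))


def adjacency(profiles: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned soft adjacency ``|Pearson r|**beta`` with zero diagonal.

    Zero-variance members are excluded with a warning.
    """
    if beta < 1:
        raise ValueError("soft power must be >= 1")
    x = profiles.to_numpy(dtype=float)
    flat = _flat_profiles(x)
    if flat.any():
        warnings.warn(f"excluding {int(flat.sum())} zero-variance members "
                      "from the network", stacklevel=2)
        profiles = profiles.loc[~flat]
        x = profiles.to_numpy(dtype=float)
    r = np.corrcoef(x)
    a = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=profiles.index, columns=profiles.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index for a connectivity vector.

    Bins ``k``, regresses ``log10 p(k)`` on ``log10 mean(k)`` over occupied
    bins, and returns R^2 signed by the negated slope sign (a positive value
    requires the decreasing degree distribution of scale-free networks).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 4 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * np.asarray(xs) + intercept
    ss_res = float(((np.asarray(ys) - fitted) ** 2).sum())
    ss_tot = float(((np.asarray(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_power(profiles: pd.DataFrame,
                    powers: tuple[int, ...] = DEFAULT_POWERS,
                    fit_threshold: float = DEFAULT_FIT_THRESHOLD) -> int:
    """Smallest soft power with a scale-free fit at or above the threshold.

    When no power qualifies — typical inside a tight co-expression cluster,
    whose degree distribution is not scale-free — the conventional default
    power for unsigned networks (6, capped to the grid) is returned with a
    warning; a degenerate all-|r|=1 correlation matrix returns the smallest
    power with a warning.
    """
    if len(profiles) < 10:
        raise ValueError("need >= 10 members to select a soft power")
    powers = tuple(sorted(powers))
    x = profiles.to_numpy(dtype=float)
    x = x[~_flat_profiles(x)]
    r = np.abs(np.corrcoef(x))
    np.fill_diagonal(r, 0.0)
    if np.allclose(r[~np.eye(len(r), dtype=bool)], 1.0):
        warnings.warn("degenerate correlation structure (all |r| = 1); "
                      "returning the smallest power", stacklevel=2)
        return powers[0]
    fits = {}
    for beta in powers:
        k = (r ** beta).sum(axis=1)
        fits[beta] = scale_free_fit(k)
        if fits[beta] >= fit_threshold:
            return beta
    fallback = min(powers, key=lambda b: abs(b - UNSIGNED_DEFAULT_POWER))
    warnings.warn(f"no power reaches scale-free fit {fit_threshold}; "
                  f"falling back to the unsigned-network default beta="
                  f"{fallback}", stacklevel=2)
    return fallback


def connectivity(profiles: pd.DataFrame, beta: float,
                 hub_fraction: float = HUB_FRACTION) -> pd.DataFrame:
    """Whole-network connectivity and hub flags for one wave.

    Returns a frame indexed by feature with ``k`` (adjacency row sums) and
    boolean ``hub`` marking the ``ceil(hub_fraction * size)`` most connected
    members; ties are broken by feature identifier order, so the hub set is
    deterministic.
    """
    a = adjacency(profiles, beta)
    k = a.sum(axis=1)
    size = len(k)
    n_hubs = math.ceil(hub_fraction * size) if size else 0
    order = sorted(k.index, key=lambda f: (-k[f], f))
    hubs = set(order[:n_hubs])
    return pd.DataFrame({"k": k, "hub": [f in hubs for f in k.index]})


@dataclass
class WaveNetwork:
    """Per-wave network summary: chosen power and member connectivity."""

    genotype: str
    wave: int
    name: str
    beta: int
    table: pd.DataFrame   # feature-indexed: k, hub

    def hub_features(self) -> set[str]:
        return set(self.table.index[self.table["hub"]])


def build_wave_networks(waveset, member_log2_means: pd.DataFrame,
                        powers: tuple[int, ...] = DEFAULT_POWERS,
                        fit_threshold: float = DEFAULT_FIT_THRESHOLD,
                        hub_fraction: float = HUB_FRACTION,
                        min_members: int = 10) -> list[WaveNetwork]:
    """One weighted network per wave of a WaveSet (waves below
    ``min_members`` are skipped with a log message)."""
    networks = []
    for w in range(waveset.n_waves):
        members = waveset.members(w)
        if len(members) < min_members:
            logger.info("%s wave %d: only %d members, skipping network",
                        waveset.genotype, w, len(members))
            continue
        profiles = member_log2_means.loc[members]
        beta = pick_soft_power(profiles, powers, fit_threshold)
        table = connectivity(profiles, beta, hub_fraction)
        networks.append(WaveNetwork(genotype=waveset.genotype, wave=w,
                                    name=waveset.names.get(w, str(w)),
                                    beta=beta, table=table))
    return networks


def _wave_phase(name: str) -> str | None:
    """Phase of a wave from its leading (strongest) peak label."""
    body = name.lstrip("+-")
    lead = body.split("+")[0].split("-")[0]
    try:
        return PHASE_MAP.get(float(lead))
    except ValueError:
        return None


def hub_overlap(wt_networks: list[WaveNetwork], onc_networks: list[WaveNetwork],
                denominator: str = "target") -> pd.DataFrame:
    """Conserved-hub fractions overall and per age phase.

    ``denominator="target"`` (default) reports the share of mutant-side hubs
    that are also WT hubs; ``"union"`` uses the Jaccard denominator.  Rows
    with an empty hub set report NaN.
    """
    if denominator not in ("target", "union"):
        raise ValueError("denominator must be 'target' or 'union'")

    def pooled(networks, phase=None):
        out: set[str] = set()
        for nw in networks:
            if phase is None or _wave_phase(nw.name) == phase:
                out |= nw.hub_features()
        return out

    rows = []
    phases = [None, "very early", "early", "middle", "late"]
    for phase in phases:
        wt = pooled(wt_networks, phase)
        onc = pooled(onc_networks, phase)
        inter = wt & onc
        if denominator == "target":
            denom = len(onc)
        else:
            denom = len(wt | onc)
        frac = (len(inter) / denom) if denom else float("nan")
        rows.append({"phase": phase or "overall", "wt_hubs": len(wt),
                     "onc_hubs": len(onc), "shared": len(inter),
                     "conserved_fraction": frac})
    return pd.DataFrame(rows).set_index("phase")


def label_tf_hubs(networks: list[WaveNetwork], tf_list: list[str],
                  contrasts: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Flag hub transcription factors and their transcriptional regulation.

    A hub is a TF when it appears in ``tf_list``; it is transcriptionally
    regulated when its BH-adjusted contrast p-value is <= ``fdr`` at one or
    more time points.  ``contrasts`` is the long-form genotype-contrast table
    (feature-indexed, ``adj_pvalue`` and ``time_months`` columns).
    """
    if not tf_list:
        raise ValueError("empty transcription-factor list")
    tf_set = set(tf_list)
    regulated = set(
        contrasts.index[contrasts["adj_pvalue"] <= fdr]
    ) if len(contrasts) else set()
    rows = []
    for nw in networks:
        for f in sorted(nw.hub_features()):
            rows.append({
                "feature": f, "genotype": nw.genotype, "wave": nw.wave,
                "wave_name": nw.name, "is_tf": f in tf_set,
                "transcriptionally_regulated": f in regulated,
            })
    return pd.DataFrame(rows)
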