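"""Soft clustering of dynamic features into named time-course expression waves.

Features that pass the dynamic gate are standardized across time-point means
and grouped by fuzzy c-means in Euclidean space (fuzzifier 1.25, membership
threshold 0.5, both from the study design this package mirrors).  The number
of waves is chosen as the largest cluster count whose centroids remain
pairwise non-overlapping (Pearson correlation below a threshold), and each
wave is named by the position(s) and direction of its expression peak(s),
e.g. ``+1+2.5+6`` or ``-12`` with the strongest peak first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FUZZIFIER = 1.25
DEFAULT_MEMBERSHIP_THRESHOLD = 0.5
DEFAULT_OVERLAP_THRESHOLD = 0.85
NAME_PROMINENCE_Z = 0.5  # |z| a centroid extremum must reach to be named
MAX_NAME_PEAKS = 3


def _format_time(tp: float) -> str:
    return f"{tp:g}"


def fuzzy_cmeans(z: np.ndarray, c: int, m: float = DEFAULT_FUZZIFIER,
                 seed: int = 0, tol: float = 1e-9, max_iter: int = 300,
                 n_restarts: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means fixed point in Euclidean space.

    Memberships ``u_fj = 1 / sum_k (d_fj / d_fk)^(2/(m-1))`` and centroids as
    ``u^m``-weighted means, iterated until the largest centroid shift falls
    below ``tol``.  Memberships are initialized uniformly at random from a
    seeded generator; ``n_restarts`` independent starts are run and the one
    with the lowest objective is kept.

    Returns ``(centroids (c, n), memberships (F, c))``.
    """
    z = np.asarray(z, dtype=float)
    n_feat = z.shape[0]
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if c >= n_feat:
        raise ValueError(f"cluster count {c} must be < number of features {n_feat}")
    if m <= 1:
        raise ValueError("fuzzifier must be > 1")

    root = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        u = rng.random((n_feat, c))
        u /= u.sum(axis=1, keepdims=True)
        centroids = np.zeros((c, z.shape[1]))
        converged = False
        for _it in range(max_iter):
            um = u ** m
            new_centroids = (um.T @ z) / um.sum(axis=0)[:, None]
            d2 = ((z[:, None, :] - new_centroids[None, :, :]) ** 2).sum(axis=2)
            u = _memberships_from_d2(d2, m)
            shift = np.abs(new_centroids - centroids).max() if _it else np.inf
            centroids = new_centroids
            if shift < tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"fuzzy c-means did not converge in {max_iter} iterations; "
                          "returning best iterate", stacklevel=2)
        obj = float(((u ** m) * d2).sum())
        if best is None or obj < best[0]:
            best = (obj, centroids, u)
    assert best is not None
    return best[1], best[2]


def _memberships_from_d2(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; exact hits get membership 1
    split across coincident centroids."""
    exponent = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore"):
        inv = d2 ** (-exponent)
    zero_rows = (d2 == 0).any(axis=1)
    u = np.empty_like(d2)
    finite = ~zero_rows
    u[finite] = inv[finite] / inv[finite].sum(axis=1, keepdims=True)
    if zero_rows.any():
        hits = (d2[zero_rows] == 0).astype(float)
        u[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    return u


def predict_memberships(z: np.ndarray, centroids: np.ndarray,
                        m: float = DEFAULT_FUZZIFIER) -> np.ndarray:
    """Membership of (possibly new) profiles against fixed centroids.

    A profile equidistant from two centroids receives membership 0.5 in
    each, directly from the membership formula.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    d2 = ((z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return _memberships_from_d2(d2, m)


def fcm_objective(z: np.ndarray, centroids: np.ndarray, u: np.ndarray,
                  m: float) -> float:
    d2 = ((np.asarray(z)[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float(((u ** m) * d2).sum())


def _centroid_correlations(centroids: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of centroid profiles; a flat centroid is
    treated as perfectly overlapping (correlation 1) so it can never justify
    a larger cluster count."""
    sd = centroids.std(axis=1)
    if (sd == 0).any():
        r = np.ones((len(centroids), len(centroids)))
        ok = sd > 0
        if ok.sum() >= 2:
            r_ok = np.corrcoef(centroids[ok])
            r[np.ix_(ok, ok)] = r_ok
        return r
    return np.corrcoef(centroids)


def select_cluster_count(z: np.ndarray, c_range: range | list[int],
                         m: float = DEFAULT_FUZZIFIER,
                         overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
                         seed: int = 0, n_restarts: int = 5) -> int:
    """Largest cluster count whose fitted centroids are pairwise non-overlapping.

    A candidate ``c`` is admissible when no pair of its centroids correlates
    at or above ``overlap_threshold``.  With no admissible candidate the
    smallest ``c`` is returned with a warning.
    """
    cs = sorted(c_range)
    if not cs:
        raise ValueError("empty cluster-count range")
    admissible = []
    for c in cs:
        centroids, _ = fuzzy_cmeans(z, c, m=m, seed=seed + c, n_restarts=n_restarts)
        r = _centroid_correlations(centroids)
        off_diag = r[~np.eye(len(r), dtype=bool)]
        if off_diag.size == 0 or off_diag.max() < overlap_threshold:
            admissible.append(c)
    if not admissible:
        warnings.warn("no cluster count yields non-overlapping centroids; "
                      f"falling back to {cs[0]}", stacklevel=2)
        return cs[0]
    return max(admissible)


def name_wave(centroid: np.ndarray, time_points: list[float],
              member_means: pd.DataFrame | None = None,
              prominence_z: float = NAME_PROMINENCE_Z,
              max_peaks: int = MAX_NAME_PEAKS) -> str:
    """Name a wave from the peak structure of its standardized centroid.

    The sign is '+' when the centroid's strongest excursion is above baseline
    and '-' when below (ties toward '+').  Peak time points are local extrema
    of the centroid with ``|z| >= prominence_z`` in the peak direction,
    ordered by decreasing peak magnitude — measured as the fold change of the
    members' mean log2 profile when ``member_means`` is given, otherwise by
    ``|z|`` — and at most ``max_peaks`` labels are used.
    """
    z = np.asarray(centroid, dtype=float)
    n = len(z)
    if n != len(time_points):
        raise ValueError("centroid length does not match time points")
    up = z.max() >= -z.min()
    sign = "+" if up else "-"
    v = z if up else -z

    peaks = [
        i for i in range(n)
        if v[i] >= prominence_z
        and (i == 0 or v[i] >= v[i - 1])
        and (i == n - 1 or v[i] >= v[i + 1])
    ]
    if not peaks:
        raise ValueError("unnameable wave: flat centroid with no peak above "
                         f"|z| = {prominence_z}")

    if member_means is not None and len(member_means) > 0:
        profile = member_means.to_numpy(dtype=float).mean(axis=0)
        if up:
            magnitude = {i: 2.0 ** (profile[i] - profile.min()) for i in peaks}
        else:
            magnitude = {i: 2.0 ** (profile.max() - profile[i]) for i in peaks}
    else:
        magnitude = {i: float(v[i]) for i in peaks}

    ordered = sorted(peaks, key=lambda i: (-magnitude[i], i))[:max_peaks]
    return "".join(f"{sign}{_format_time(time_points[i])}" for i in ordered)


@dataclass
class WaveSet:
    """Fitted expression waves for one genotype.

    ``assignment`` maps each clustered feature to a wave index, or -1 when its
    best membership is below ``membership_threshold`` (unassigned).
    """

    genotype: str
    time_points: list[float]
    centroids: np.ndarray            # (c, n) on the standardized scale
    memberships: pd.DataFrame        # features x c
    assignment: pd.Series            # feature -> wave index or -1
    names: dict[int, str]
    fuzzifier: float = DEFAULT_FUZZIFIER
    membership_threshold: float = DEFAULT_MEMBERSHIP_THRESHOLD
    sizes: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        counts = self.assignment[self.assignment >= 0].value_counts()
        self.sizes = {w: int(counts.get(w, 0)) for w in range(len(self.centroids))}

    @property
    def n_waves(self) -> int:
        return len(self.centroids)

    def members(self, wave: int) -> list[str]:
        return list(self.assignment.index[self.assignment == wave])

    def assigned_features(self) -> list[str]:
        return list(self.assignment.index[self.assignment >= 0])

    def to_frame(self) -> pd.DataFrame:
        best = self.memberships.to_numpy().max(axis=1)
        return pd.DataFrame({
            "wave": self.assignment,
            "name": [self.names.get(w, "") if w >= 0 else ""
                     for w in self.assignment],
            "membership": best,
        }, index=self.assignment.index)


def save_waveset(ws: WaveSet, out_dir) -> None:
    """Persist a WaveSet as centroids.csv / memberships.csv / assignment.csv
    plus a small meta.json."""
    import json
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ws.centroids, columns=[f"{t:g}" for t in ws.time_points]
                 ).to_csv(out / "centroids.csv", index_label="wave")
    ws.memberships.to_csv(out / "memberships.csv", index_label="feature")
    ws.to_frame().to_csv(out / "assignment.csv", index_label="feature")
    meta = {"genotype": ws.genotype, "fuzzifier": ws.fuzzifier,
            "membership_threshold": ws.membership_threshold,
            "time_points": ws.time_points,
            "names": {str(k): v for k, v in ws.names.items()}}
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def load_waveset(in_dir) -> WaveSet:
    import json
    from pathlib import Path
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    centroids = pd.read_csv(src / "centroids.csv", index_col="wave")
    memberships = pd.read_csv(src / "memberships.csv", index_col="feature")
    assignment = pd.read_csv(src / "assignment.csv", index_col="feature")["wave"]
    return WaveSet(genotype=meta["genotype"],
                   time_points=[float(t) for t in meta["time_points"]],
                   centroids=centroids.to_numpy(),
                   memberships=memberships, assignment=assignment,
                   names={int(k): v for k, v in meta["names"].items()},
                   fuzzifier=meta["fuzzifier"],
                   membership_threshold=meta["membership_threshold"])


def assign_memberships(memberships: pd.DataFrame,
                       threshold: float = DEFAULT_MEMBERSHIP_THRESHOLD) -> pd.Series:
    """Argmax assignment gated by the membership threshold (-1 = unassigned)."""
    u = memberships.to_numpy()
    best = u.argmax(axis=1)
    ok = u.max(axis=1) >= threshold
    return pd.Series(np.where(ok, best, -1), index=memberships.index, name="wave")


def build_waveset(z: pd.DataFrame, genotype: str,
                  member_log2_means: pd.DataFrame | None = None,
                  c: int | None = None,
                  c_range: range | list[int] = range(2, 13),
                  m: float = DEFAULT_FUZZIFIER,
                  membership_threshold: float = DEFAULT_MEMBERSHIP_THRESHOLD,
                  overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
                  seed: int = 0, n_restarts: int = 10) -> WaveSet:
    """Cluster standardized dynamic-feature profiles into a named WaveSet.

    ``z`` is the features x time-points frame of standardized profiles
    (dynamic features only); ``member_log2_means`` the matching log2
    time-point means used for peak-magnitude ordering in names.  When ``c``
    is not given it is chosen by :func:`select_cluster_count` over
    ``c_range``.
    """
    time_points = [float(t) for t in z.columns]
    if c is None:
        c = select_cluster_count(z.to_numpy(), c_range, m=m,
                                 overlap_threshold=overlap_threshold, seed=seed)
        logger.info("%s: selected %d waves from range %s", genotype, c, list(c_range))
    centroids, u = fuzzy_cmeans(z.to_numpy(), c, m=m, seed=seed,
                                n_restarts=n_restarts)
    memberships = pd.DataFrame(u, index=z.index,
                               columns=[f"wave_{k}" for k in range(c)])
    assignment = assign_memberships(memberships, membership_threshold)

    names: dict[int, str] = {}
    for w in range(c):
        members = assignment.index[assignment == w]
        mm = (member_log2_means.loc[members]
              if member_log2_means is not None and len(members) else None)
        try:
            names[w] = name_wave(centroids[w], time_points, member_means=mm)
        except ValueError:
            names[w] = f"flat_{w}"
            logger.warning("%s wave %d has no nameable peak", genotype, w)
    return WaveSet(genotype=genotype, time_points=time_points,
                   centroids=centroids, memberships=memberships,
                   assignment=assignment, names=names, fuzzifier=m,
                   membership_threshold=membership_threshold)
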