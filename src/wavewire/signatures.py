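"""Gene-signature behavior over the time course.

Four analyses live here:

* single-sample GSEA (ssGSEA): a rank-based running-sum enrichment score per
  sample, averaged within (genotype, time point) into a six-point enrichment
  profile per signature;
* intra-signature co-expression typing: the distribution of pairwise Pearson
  correlations between member genes' temporal profiles is classified into
  type 1 (centered at 0, no stable co-expression), type 2 (skewed positive,
  co-regulated), type 3 (skewed negative, anti-regulated) or type 4 (bimodal,
  opposing co-regulated subsets);
* Kolmogorov-Smirnov comparison of r distributions between genotypes;
* inter-signature functional clusters: maximal cliques of the graph whose
  edges join signature enrichment profiles with a significant (p <= 0.05)
  pairwise Pearson correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionStudy, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_SSGSEA_ALPHA = 0.25
DEFAULT_FRAC_THRESHOLD = 0.2


def _flat_rows(x: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Rows with no real temporal variance (tolerance absorbs the ulp-level
    jitter that averaging identical replicates can leave behind)."""
    sd = x.std(axis=1)
    return sd <= rtol * (1.0 + np.abs(x.mean(axis=1)))


def ssgsea(values: np.ndarray, feature_ids: list[str], gene_set: list[str],
           alpha: float = DEFAULT_SSGSEA_ALPHA) -> float:
    """ssGSEA running-sum enrichment score for one expression profile.

    Features are ranked by expression (descending).  Walking down the
    ranking, the score accumulates the difference between the weighted
    in-set ECDF (weights ``|value|**alpha``) and the unweighted out-of-set
    ECDF.  Zero overlap between the set and the profile is an error.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    in_set = np.isin(np.asarray(feature_ids), list(gene_set))
    if not in_set.any():
        raise ValueError(f"gene set has no overlap with the profile "
                         f"(size {len(set(gene_set))})")
    if in_set.all():
        raise ValueError("gene set covers the entire profile; score undefined")
    order = np.argsort(-values, kind="stable")
    ranked_in = in_set[order]
    ranked_w = np.abs(values[order]) ** alpha

    w_in = np.where(ranked_in, ranked_w, 0.0)
    denom_in = w_in.sum()
    p_in = np.cumsum(w_in) / denom_in if denom_in > 0 else np.cumsum(ranked_in) / ranked_in.sum()
    p_out = np.cumsum(~ranked_in) / (n - ranked_in.sum())
    return float((p_in - p_out).sum())


def ssgsea_matrix(study: ExpressionStudy, sets: GeneSetCollection,
                  alpha: float = DEFAULT_SSGSEA_ALPHA) -> pd.DataFrame:
    """Per-sample ssGSEA scores, one row per signature, one column per sample."""
    rows = {}
    for name, members in sets.sets.items():
        scores = [
            ssgsea(study.values[:, j], study.features, members, alpha=alpha)
            for j in range(len(study.samples))
        ]
        rows[name] = scores
    return pd.DataFrame(rows, index=study.samples).T


def normalize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Normalize enrichment scores by the overall score range (the originating
    method's convention for comparing scores across samples and sets)."""
    span = float(scores.to_numpy().max() - scores.to_numpy().min())
    if span == 0:
        warnings.warn("all enrichment scores identical; skipping normalization",
                      stacklevel=2)
        return scores.copy()
    return scores / span


def enrichment_profiles(study: ExpressionStudy, sets: GeneSetCollection,
                        genotype: str, alpha: float = DEFAULT_SSGSEA_ALPHA,
                        normalize: bool = True,
                        per_sample: pd.DataFrame | None = None) -> pd.DataFrame:
    """Time-course enrichment profiles for one genotype.

    ssGSEA is computed per sample and averaged within each (genotype, time
    point), giving one score per time point per signature (rows = signatures,
    columns = time points).  Pass ``per_sample`` to reuse an existing
    :func:`ssgsea_matrix` result.
    """
    scores = ssgsea_matrix(study, sets, alpha=alpha) if per_sample is None else per_sample
    if normalize:
        scores = normalize_scores(scores)
    cols = {}
    for tp in study.time_points:
        mask = study.sample_mask(genotype, tp)
        cols[tp] = scores.loc[:, mask].mean(axis=1)
    return pd.DataFrame(cols)


def pearson_r_crit(n: int, alpha: float = 0.05) -> float:
    """Two-sided significance bound on Pearson r at sample size ``n``.

    Inverts ``t = r sqrt((n-2)/(1-r^2))`` against the t(n-2) quantile; at
    n = 6, alpha = 0.05 this is 0.811.
    """
    if n < 3:
        raise ValueError("need n >= 3 for a correlation significance bound")
    t = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t / np.sqrt(t * t + n - 2))


@dataclass
class CoexpressionTyping:
    """Pairwise temporal-correlation summary for one signature/genotype."""

    signature: str
    genotype: str
    r_values: np.ndarray      # upper-triangle pairwise Pearson r
    r_matrix: pd.DataFrame
    f_plus: float
    f_minus: float
    type: int
    r_crit: float


def classify_r_distribution(r_values: np.ndarray, r_crit: float,
                            frac_threshold: float = DEFAULT_FRAC_THRESHOLD
                            ) -> tuple[float, float, int]:
    """Classify an r distribution into the four synchronization types.

    ``f_plus`` / ``f_minus`` are the fractions of pairs significantly
    positive (r >= r_crit) / negative (r <= -r_crit).  Type 2 when only
    ``f_plus`` reaches ``frac_threshold``, type 3 when only ``f_minus``
    does, type 4 when both do (bimodal), type 1 otherwise.
    """
    r = np.asarray(r_values, dtype=float)
    if r.size == 0:
        raise ValueError("no correlation pairs to classify")
    f_plus = float((r >= r_crit).mean())
    f_minus = float((r <= -r_crit).mean())
    plus = f_plus >= frac_threshold
    minus = f_minus >= frac_threshold
    if plus and minus:
        kind = 4
    elif plus:
        kind = 2
    elif minus:
        kind = 3
    else:
        kind = 1
    return f_plus, f_minus, kind


def intra_signature_typing(study: ExpressionStudy, genotype: str,
                           signature: str, members: list[str],
                           r_crit_alpha: float = 0.05,
                           frac_threshold: float = DEFAULT_FRAC_THRESHOLD
                           ) -> CoexpressionTyping:
    """Type one signature's intra-set temporal co-expression in one genotype.

    Member time-point mean profiles (n = 6 points) are pairwise Pearson
    correlated; members with zero temporal variance are dropped with a
    warning.  Needs >= 3 usable members.
    """
    present = [m for m in members if m in set(study.features)]
    if len(present) < 3:
        raise ValueError(f"signature {signature!r}: fewer than 3 members present")
    means = study.time_point_means(genotype).loc[present]
    flat = _flat_rows(means.to_numpy())
    if flat.any():
        dropped = [f for f, is_flat in zip(present, flat) if is_flat]
        warnings.warn(f"signature {signature!r}: dropping {len(dropped)} "
                      "zero-variance members", stacklevel=2)
        means = means.loc[[f for f in present if f not in set(dropped)]]
        if len(means) < 3:
            raise ValueError(f"signature {signature!r}: fewer than 3 members "
                             "with temporal variance")
    r = np.corrcoef(means.to_numpy())
    iu = np.triu_indices(len(means), k=1)
    r_vals = r[iu]
    n_tp = means.shape[1]
    r_crit = pearson_r_crit(n_tp, r_crit_alpha)
    f_plus, f_minus, kind = classify_r_distribution(r_vals, r_crit, frac_threshold)
    return CoexpressionTyping(
        signature=signature, genotype=genotype, r_values=r_vals,
        r_matrix=pd.DataFrame(r, index=means.index, columns=means.index),
        f_plus=f_plus, f_minus=f_minus, type=kind, r_crit=r_crit)


def type_all_signatures(study: ExpressionStudy, sets: GeneSetCollection,
                        genotype: str, r_crit_alpha: float = 0.05,
                        frac_threshold: float = DEFAULT_FRAC_THRESHOLD
                        ) -> pd.DataFrame:
    rows = []
    for name, members in sets.sets.items():
        try:
            t = intra_signature_typing(study, genotype, name, members,
                                       r_crit_alpha, frac_threshold)
        except ValueError as exc:
            logger.warning("skipping signature %s: %s", name, exc)
            continue
        rows.append({"signature": name, "genotype": genotype,
                     "f_plus": t.f_plus, "f_minus": t.f_minus, "type": t.type})
    return pd.DataFrame(rows).set_index("signature")


def compare_r_distributions(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic ``D = sup |ECDF_a - ECDF_b|`` with asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class SignatureClusterSet:
    correlation: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame      # boolean mask, p <= alpha
    clusters: list[list[str]]      # maximal cliques, largest first


def signature_clusters(profiles: pd.DataFrame, alpha: float = 0.05
                       ) -> SignatureClusterSet:
    """Functional clusters of signatures from their enrichment profiles.

    Signatures (rows of ``profiles``) are pairwise Pearson-correlated over
    their time-course enrichment scores; pairs with p <= ``alpha`` form edges
    and clusters are the maximal cliques of that graph (every within-cluster
    pair significant), reported largest first.  Constant profiles are
    excluded with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 enrichment profiles")
    flat = _flat_rows(profiles.to_numpy())
    if flat.any():
        dropped = list(profiles.index[flat])
        warnings.warn(f"excluding constant enrichment profiles: {dropped}",
                      stacklevel=2)
        profiles = profiles.loc[~flat]
    names = list(profiles.index)
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ri, pi = stats.pearsonr(profiles.iloc[i], profiles.iloc[j])
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
    sig = (p <= alpha) & ~np.eye(k, dtype=bool)
    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(k):
        for j in range(i + 1, k):
            if sig[i, j]:
                g.add_edge(names[i], names[j])
    cliques = [sorted(c) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (-len(c), c))
    idx = pd.Index(names, name="signature")
    return SignatureClusterSet(
        correlation=pd.DataFrame(r, index=idx, columns=idx),
        pvalues=pd.DataFrame(p, index=idx, columns=idx),
        significant=pd.DataFrame(sig, index=idx, columns=idx),
        clusters=cliques)
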