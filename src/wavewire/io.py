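"""Reading and writing of expression studies, gene-set collections and networks.

The on-disk formats are plain text: a TSV expression matrix (features x
samples, header row of sample identifiers, first column of feature
identifiers), a TSV sample design (columns ``sample``, ``genotype``,
``time_months``, ``replicate``), GMT gene-set collections, and GraphML/JSON
graph exports.  Expression values are log2-scale normalized intensities; any
upstream probe summarization (e.g. RMA) is assumed to have happened already.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Time points (months of age) the study design supports.
TIME_POINTS: tuple[float, ...] = (0.6, 1.0, 2.5, 4.0, 6.0, 12.0)


class LoadError(ValueError):
    """Raised when an input file fails validation."""


@dataclass
class ExpressionStudy:
    """A log2 expression matrix together with its sample design.

    Parameters
    ----------
    features
        Ordered feature identifiers (probe sets or gene symbols); unique.
    samples
        Ordered sample identifiers, matching the matrix columns.
    values
        ``(n_features, n_samples)`` array of log2 intensities, no NaN.
    design
        One row per sample with columns ``sample``, ``genotype``,
        ``time_months``, ``replicate``; row order matches ``samples``.
    """

    features: list[str]
    samples: list[str]
    values: np.ndarray
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise LoadError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if len(set(self.features)) != len(self.features):
            dupes = sorted({f for f in self.features if self.features.count(f) > 1})
            raise LoadError(f"duplicate feature identifiers: {dupes[:5]}")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise LoadError(
                f"missing value at feature {self.features[i]!r}, "
                f"sample {self.samples[j]!r}"
            )
        if list(self.design["sample"]) != list(self.samples):
            raise LoadError("design row order does not match sample order")
        bad_tp = sorted(set(self.design["time_months"]) - set(TIME_POINTS))
        if bad_tp:
            raise LoadError(
                f"unknown time points {bad_tp}; allowed: {list(TIME_POINTS)}"
            )
        # replicate coverage: every (genotype, time) cell needs >= 2 replicates
        counts = self.design.groupby(["genotype", "time_months"]).size()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise LoadError(f"fewer than 2 replicates in design cells {bad}")
        if (counts < 3).any():
            warnings.warn(
                "some (genotype, time point) cells have fewer than 3 replicates",
                stacklevel=2,
            )

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.design["genotype"].unique())

    @property
    def time_points(self) -> list[float]:
        return sorted(self.design["time_months"].unique())

    def feature_index(self) -> pd.Index:
        return pd.Index(self.features, name="feature")

    def sample_mask(self, genotype: str, time_months: float | None = None) -> np.ndarray:
        m = (self.design["genotype"] == genotype).to_numpy()
        if time_months is not None:
            m &= (self.design["time_months"] == time_months).to_numpy()
        return m

    def time_point_means(self, genotype: str) -> pd.DataFrame:
        """Per-feature replicate means at each time point of one genotype.

        Returns a ``features x time_points`` frame of log2-scale means.
        """
        cols = {}
        for tp in self.time_points:
            mask = self.sample_mask(genotype, tp)
            if not mask.any():
                continue
            cols[tp] = self.values[:, mask].mean(axis=1)
        if not cols:
            raise LoadError(f"no samples for genotype {genotype!r}")
        return pd.DataFrame(cols, index=self.feature_index())

    def subset_features(self, keep: list[str]) -> "ExpressionStudy":
        idx = pd.Index(self.features).get_indexer(keep)
        if (idx < 0).any():
            missing = [k for k, i in zip(keep, idx) if i < 0]
            raise LoadError(f"features not in study: {missing[:5]}")
        return ExpressionStudy(
            features=list(keep),
            samples=list(self.samples),
            values=self.values[idx, :],
            design=self.design.reset_index(drop=True),
        )


@dataclass
class GeneSetCollection:
    """Named collection of gene sets (GMT semantics, order preserved)."""

    name: str
    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sname, members in self.sets.items():
            if not members:
                raise LoadError(f"gene set {sname!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict_to(self, features: list[str] | pd.Index) -> "GeneSetCollection":
        universe = set(features)
        kept = {
            n: [g for g in m if g in universe]
            for n, m in self.sets.items()
        }
        kept = {n: m for n, m in kept.items() if m}
        return GeneSetCollection(name=self.name, sets=kept)


def read_expression(matrix_path: str | Path, design_path: str | Path,
                    drop_missing: bool = False) -> ExpressionStudy:
    """Load an expression matrix TSV and its design TSV into a study.

    Samples present in only one of the two files raise a :class:`LoadError`
    naming the sample; matrix columns are reordered to the design order.
    Non-numeric matrix cells raise with their row and column.  With
    ``drop_missing=True`` features containing missing values are dropped
    instead of failing the load.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    design = pd.read_csv(design_path, sep="\t")
    required = {"sample", "genotype", "time_months", "replicate"}
    if not required <= set(design.columns):
        raise LoadError(f"design lacks columns {sorted(required - set(design.columns))}")
    design["sample"] = design["sample"].astype(str)
    design["time_months"] = design["time_months"].astype(float)
    design["replicate"] = design["replicate"].astype(int)

    mat_samples = set(map(str, mat.columns))
    des_samples = set(design["sample"])
    only_design = sorted(des_samples - mat_samples)
    if only_design:
        raise LoadError(f"sample {only_design[0]!r} in design but not in matrix")
    only_matrix = sorted(mat_samples - des_samples)
    if only_matrix:
        raise LoadError(f"sample {only_matrix[0]!r} in matrix but not in design")

    mat = mat[list(design["sample"])]
    values = np.empty(mat.shape, dtype=float)
    for j, col in enumerate(mat.columns):
        try:
            # astype(float) parses via correctly-rounded float(); pandas'
            # fast to_numeric parser can be off by one ulp
            values[:, j] = mat[col].astype(float)
        except (ValueError, TypeError):
            parsed = pd.to_numeric(mat[col], errors="coerce")
            i = int(np.argwhere(parsed.isna().to_numpy())[0])
            raise LoadError(
                f"non-numeric value {mat[col].iloc[i]!r} at feature "
                f"{mat.index[i]!r}, sample {col!r}"
            ) from None

    features = [str(f) for f in mat.index]
    if np.isnan(values).any() and drop_missing:
        keep = ~np.isnan(values).any(axis=1)
        logger.warning("dropping %d features with missing values", int((~keep).sum()))
        features = [f for f, k in zip(features, keep) if k]
        values = values[keep]
    return ExpressionStudy(features=features, samples=list(design["sample"]),
                           values=values, design=design.reset_index(drop=True))


def write_expression(study: ExpressionStudy, matrix_path: str | Path,
                     design_path: str | Path) -> None:
    """Write a study back to the matrix/design TSV pair (full precision)."""
    frame = pd.DataFrame(study.values, index=pd.Index(study.features, name="feature"),
                         columns=study.samples)
    frame.to_csv(matrix_path, sep="\t")
    study.design.to_csv(design_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a set are de-duplicated with a logged warning;
    lines with fewer than three fields raise with the line number.
    """
    sets: dict[str, list[str]] = {}
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(f"{path.name}:{lineno}: GMT line has "
                                f"{len(fields)} fields, need >= 3")
            name = fields[0]
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning("%s:%d: duplicate member %r in set %r",
                                   path.name, lineno, g, name)
                    continue
                seen.add(g)
                members.append(g)
            sets[name] = members
    if not sets:
        logger.warning("%s: empty GMT file", path.name)
    return GeneSetCollection(name=path.stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.name, *members]) + "\n")


def read_feature_list(path: str | Path) -> list[str]:
    """One feature identifier per line; blank lines and '#' comments skipped."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.append(token)
    return out


def write_network(graph: nx.DiGraph, path: str | Path, format: str = "graphml") -> None:
    """Export a flow/hub network to GraphML or JSON node-link text."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "json":
        payload = nx.node_link_data(graph, edges="edges")
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unsupported network format {format!r}; use graphml or json")


def read_network(path: str | Path, format: str = "graphml") -> nx.DiGraph:
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "json":
        return nx.node_link_graph(json.loads(path.read_text()), edges="edges")
    raise ValueError(f"unsupported network format {format!r}; use graphml or json")
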