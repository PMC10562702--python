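"""Synthetic two-genotype time-course expression studies with known truth.

The generator emulates the structure of an RMA-style log2 microarray study
of two genotypes (WT and a constitutively active mutant, "Onc") sampled in
triplicate at six ages (0.6, 1, 2.5, 4, 6 and 12 months), with planted:

* expression waves — six temporal profiles per genotype (single-peak,
  bimodal and down-regulated shapes), each feature's log2 signal being
  ``baseline + sign * amplitude * shape(t)``;
* a cross-genotype flow map — of each WT wave's members, 60% keep a wave in
  the mutant (same index), 20% move to the next wave and 20% lose their
  dynamics; each mutant wave additionally gains mutant-only members;
* hub blocks — the top decile of each wave shares a latent temporal factor
  and carries no private wobble, making it the most connected core of the
  wave's co-expression network, while ordinary members carry a private
  temporal wobble that decorrelates the bulk;
* gene signatures — co-regulated (type 2, one wave's hub core), bimodal
  (type 4, two anti-correlated waves' cores) and unsynchronized (type 1,
  stable features with independent wobble).

Every structured perturbation (wobble, hub latent) scales with ``noise_sd``,
so a zero-noise study is exactly clean: replicates are identical and all
planted calls are recoverable without error.  Truth is returned as a
machine-readable object and can be serialized next to the matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import ExpressionStudy, GeneSetCollection, TIME_POINTS

# temporal shape templates (values at the six time points, min 0, peak 1)
_SHAPES: dict[str, list[float]] = {
    "peak_0.6":   [1.0, 0.30, 0.05, 0.00, 0.00, 0.00],
    "peak_2.5":   [0.0, 0.25, 1.00, 0.30, 0.05, 0.00],
    "peaks_1_6":  [0.1, 1.00, 0.20, 0.10, 0.75, 0.05],
    "peak_12":    [0.0, 0.00, 0.05, 0.15, 0.40, 1.00],
    "peak_6":     [0.0, 0.05, 0.20, 0.35, 1.00, 0.30],
}

#: (shape key, sign) per wave index, per genotype.  Waves 1 and 5 are exact
#: anti-profiles within each genotype (allowed: the non-overlap criterion
#: only rejects positively correlated centroids) and the flow map sends the
#: WT anti-pair onto the mutant anti-pair, which is what lets a bimodal
#: (type 4) signature stay bimodal in both genotypes.
WAVE_PLAN: dict[str, list[tuple[str, int]]] = {
    "WT": [("peak_0.6", +1), ("peak_2.5", +1), ("peaks_1_6", +1),
           ("peak_12", -1), ("peak_6", +1), ("peak_2.5", -1)],
    "Onc": [("peak_0.6", +1), ("peaks_1_6", +1), ("peak_2.5", -1),
            ("peak_6", +1), ("peak_12", -1), ("peaks_1_6", -1)],
}


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the study conditions this package
    mirrors (2 genotypes x 6 time points x 3 replicates)."""

    n_features: int = 2000
    n_waves: int = 6
    wt_wave_size: int = 150          # WT members per wave
    stay_fraction: float = 0.6       # keep the same wave index in the mutant
    move_fraction: float = 0.2       # move to the next wave in the mutant
    onc_only_per_wave: int = 100     # mutant-only members added per wave
    n_replicates: int = 3
    amplitude: float = 1.5           # planted peak-to-trough, log2 units
    noise_sd: float = 0.25           # replicate noise, log2 units
    baseline_range: tuple[float, float] = (6.0, 10.0)
    jitter_scale: float = 1.4        # private wobble sd, units of noise_sd
    hub_latent_scale: float = 0.0    # optional hub shared factor, units of noise_sd
    hub_fraction: float = 0.10
    n_type1_signatures: int = 3
    type1_signature_size: int = 15

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.stay_fraction + self.move_fraction > 1:
            raise ValueError("stay + move fractions exceed 1")
        needed = (self.n_waves * (self.wt_wave_size + self.onc_only_per_wave)
                  + self.n_type1_signatures * self.type1_signature_size)
        if self.n_features < needed:
            raise ValueError(f"n_features={self.n_features} too small; "
                             f"need >= {needed}")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated study."""

    config: SimulationConfig
    seed: int
    features: list[str]
    wave_assignment: dict[str, dict[str, int]]   # genotype -> feature -> wave
    hub_features: dict[str, dict[int, list[str]]]  # genotype -> wave -> hubs
    flow_edges: list[tuple[int, int, int]]       # (wt wave, onc wave, count)
    signature_sets: dict[str, list[str]]
    signature_types: dict[str, int]
    jittered_static: list[str]
    wave_names: dict[str, dict[int, str]] = field(default_factory=dict)

    def dynamic_features(self, genotype: str) -> set[str]:
        return set(self.wave_assignment[genotype])

    def wave_members(self, genotype: str, wave: int) -> set[str]:
        return {f for f, w in self.wave_assignment[genotype].items() if w == wave}

    def all_hubs(self, genotype: str) -> set[str]:
        out: set[str] = set()
        for members in self.hub_features[genotype].values():
            out |= set(members)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "seed": self.seed,
            "features": self.features,
            "wave_assignment": self.wave_assignment,
            "hub_features": {g: {str(w): m for w, m in d.items()}
                             for g, d in self.hub_features.items()},
            "flow_edges": self.flow_edges,
            "signature_sets": self.signature_sets,
            "signature_types": self.signature_types,
            "jittered_static": self.jittered_static,
            "wave_names": {g: {str(w): n for w, n in d.items()}
                           for g, d in self.wave_names.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        cfg_raw = raw["config"]
        cfg_raw["baseline_range"] = tuple(cfg_raw["baseline_range"])
        return cls(
            config=SimulationConfig(**cfg_raw),
            seed=raw["seed"],
            features=raw["features"],
            wave_assignment=raw["wave_assignment"],
            hub_features={g: {int(w): m for w, m in d.items()}
                          for g, d in raw["hub_features"].items()},
            flow_edges=[tuple(e) for e in raw["flow_edges"]],
            signature_sets=raw["signature_sets"],
            signature_types=raw["signature_types"],
            jittered_static=raw["jittered_static"],
            wave_names={g: {int(w): n for w, n in d.items()}
                        for g, d in raw.get("wave_names", {}).items()},
        )


def _fixed_norm_wobble(rng: np.random.Generator, n_tp: int, sd: float,
                       shape: np.ndarray | None = None) -> np.ndarray:
    """Private temporal wobble: fixed magnitude ``sqrt(n_tp) * sd``, random
    direction orthogonal to the constant vector and (when given) to the
    centered wave shape.

    Correlation is blind to the constant component and barely weakened by a
    component parallel to the shared shape, so drawing the wobble inside the
    complementary subspace at fixed magnitude gives every ordinary member the
    same amount of *effective* idiosyncrasy.  Hub identity then reflects the
    planted block structure instead of which member happened to draw a small
    or shape-aligned wobble."""
    if sd == 0:
        return np.zeros(n_tp)
    basis = [np.ones(n_tp) / np.sqrt(n_tp)]
    if shape is not None:
        centered = shape - shape.mean()
        norm = np.linalg.norm(centered)
        if norm > 0:
            basis.append(centered / norm)
    v = rng.normal(0.0, 1.0, size=n_tp)
    for b in basis:
        v -= (v @ b) * b
    return v * (np.sqrt(n_tp) * sd / np.linalg.norm(v))


def wave_profile(genotype: str, wave: int, amplitude: float) -> np.ndarray:
    """Planted log2 deviation-from-baseline profile of one wave.

    The shape template is rescaled to span exactly [0, 1] so the planted
    peak-to-trough amplitude equals ``amplitude`` log2 units precisely.
    """
    shape_key, sign = WAVE_PLAN[genotype][wave]
    s = np.asarray(_SHAPES[shape_key], dtype=float)
    s = (s - s.min()) / (s.max() - s.min())
    return sign * amplitude * s


def generate(config: SimulationConfig | None = None, seed: int = 0
             ) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Generate a study and its truth; bitwise deterministic given the seed."""
    cfg = config or SimulationConfig()
    if cfg.n_waves > len(WAVE_PLAN["WT"]):
        raise ValueError(f"at most {len(WAVE_PLAN['WT'])} waves are defined")
    rng = np.random.default_rng(seed)
    n_tp = len(TIME_POINTS)
    width = len(str(cfg.n_features - 1))
    features = [f"F{i:0{width}d}" for i in range(cfg.n_features)]

    n_stay = round(cfg.stay_fraction * cfg.wt_wave_size)
    n_move = round(cfg.move_fraction * cfg.wt_wave_size)

    wave_assignment: dict[str, dict[str, int]] = {"WT": {}, "Onc": {}}
    next_free = 0
    wt_members: dict[int, list[str]] = {}
    for w in range(cfg.n_waves):
        members = features[next_free:next_free + cfg.wt_wave_size]
        next_free += cfg.wt_wave_size
        wt_members[w] = members
        for f in members:
            wave_assignment["WT"][f] = w
        for f in members[:n_stay]:
            wave_assignment["Onc"][f] = w
        for f in members[n_stay:n_stay + n_move]:
            wave_assignment["Onc"][f] = (w + 1) % cfg.n_waves
        # the remainder is WT-only (static in the mutant)
    onc_only: dict[int, list[str]] = {}
    for w in range(cfg.n_waves):
        members = features[next_free:next_free + cfg.onc_only_per_wave]
        next_free += cfg.onc_only_per_wave
        onc_only[w] = members
        for f in members:
            wave_assignment["Onc"][f] = w

    # hub blocks: WT, the first decile of each wave; mutant, the shared
    # stayer core plus the leading mutant-only members
    n_wt_hub = int(np.ceil(cfg.hub_fraction * cfg.wt_wave_size))
    onc_wave_size = n_stay + n_move + cfg.onc_only_per_wave
    n_onc_hub = int(np.ceil(cfg.hub_fraction * onc_wave_size))
    n_shared_hub = min(n_wt_hub, max(2, n_onc_hub - n_onc_hub // 2))
    hub_features: dict[str, dict[int, list[str]]] = {"WT": {}, "Onc": {}}
    for w in range(cfg.n_waves):
        hub_features["WT"][w] = wt_members[w][:n_wt_hub]
        extra = n_onc_hub - n_shared_hub
        hub_features["Onc"][w] = wt_members[w][:n_shared_hub] + onc_only[w][:extra]

    # planted flow edges under the 10%-of-source rule
    flow_edges: list[tuple[int, int, int]] = []
    threshold = int(np.ceil(0.10 * cfg.wt_wave_size))
    for w in range(cfg.n_waves):
        if n_stay >= threshold:
            flow_edges.append((w, w, n_stay))
        if n_move >= threshold:
            flow_edges.append((w, (w + 1) % cfg.n_waves, n_move))

    # signatures: type 2 from single-wave hub cores, type 4 from the
    # anti-correlated wave pair (1, 5), type 1 from wobbling stable features
    signature_sets: dict[str, list[str]] = {}
    signature_types: dict[str, int] = {}
    core = {w: hub_features["Onc"][w][:n_shared_hub] for w in range(cfg.n_waves)}
    for j, w in enumerate([0, 2, 3, 4][:cfg.n_waves]):
        name = f"SIG_COREG_{j + 1}"
        signature_sets[name] = list(core[w])
        signature_types[name] = 2
    if cfg.n_waves >= 6:
        half = n_shared_hub // 2
        signature_sets["SIG_BIMODAL_1"] = core[1][:half] + core[5][:half]
        signature_sets["SIG_BIMODAL_2"] = core[1][half:] + core[5][half:]
        signature_types["SIG_BIMODAL_1"] = 4
        signature_types["SIG_BIMODAL_2"] = 4
    jittered_static: list[str] = []
    for j in range(cfg.n_type1_signatures):
        members = features[next_free:next_free + cfg.type1_signature_size]
        next_free += cfg.type1_signature_size
        name = f"SIG_UNSYNC_{j + 1}"
        signature_sets[name] = members
        signature_types[name] = 1
        jittered_static.extend(members)

    # --- assemble the log2 matrix -------------------------------------
    baselines = rng.uniform(*cfg.baseline_range, size=cfg.n_features)
    genotypes = ["WT", "Onc"]
    samples, design_rows = [], []
    for g in genotypes:
        for tp in TIME_POINTS:
            for rep in range(1, cfg.n_replicates + 1):
                samples.append(f"{g}_{tp:g}M_r{rep}")
                design_rows.append({"sample": samples[-1], "genotype": g,
                                    "time_months": tp, "replicate": rep})
    design = pd.DataFrame(design_rows)

    feat_pos = {f: i for i, f in enumerate(features)}
    jitter_sd = cfg.jitter_scale * cfg.noise_sd
    latent_sd = cfg.hub_latent_scale * cfg.noise_sd

    values = np.empty((cfg.n_features, len(samples)))
    col = 0
    for g in genotypes:
        profile = np.tile(baselines[:, None], (1, n_tp))
        hubs_g = {f for mm in hub_features[g].values() for f in mm}
        latents = {w: _fixed_norm_wobble(rng, n_tp, latent_sd,
                                         wave_profile(g, w, cfg.amplitude))
                   for w in range(cfg.n_waves)}
        # hub-block members follow their wave's temporal program exactly
        # (plus an optional shared latent); ordinary members add a private
        # wobble, which is what makes the hub block the wave's most
        # connected common denominator
        for f, w in wave_assignment[g].items():
            i = feat_pos[f]
            shape = wave_profile(g, w, cfg.amplitude)
            profile[i] += shape
            if f in hubs_g:
                profile[i] += latents[w]
            else:
                profile[i] += _fixed_norm_wobble(rng, n_tp, jitter_sd, shape)
        for f in jittered_static:
            profile[feat_pos[f]] += _fixed_norm_wobble(rng, n_tp, jitter_sd)
        for _tp_idx in range(n_tp):
            for _rep in range(cfg.n_replicates):
                noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_features) \
                    if cfg.noise_sd > 0 else 0.0
                values[:, col] = profile[:, _tp_idx] + noise
                col += 1

    study = ExpressionStudy(features=features, samples=samples,
                            values=values, design=design)
    truth = SyntheticTruth(
        config=cfg, seed=seed, features=features,
        wave_assignment=wave_assignment, hub_features=hub_features,
        flow_edges=flow_edges, signature_sets=signature_sets,
        signature_types=signature_types, jittered_static=jittered_static)
    return study, truth


def truth_gene_sets(truth: SyntheticTruth) -> GeneSetCollection:
    return GeneSetCollection(name="planted", sets=dict(truth.signature_sets))


# ---------------------------------------------------------------- recovery

def _map_fitted_to_planted(waveset, truth: SyntheticTruth, genotype: str
                           ) -> dict[int, int]:
    """Match each fitted wave to the planted wave sharing the most members."""
    mapping = {}
    for w in range(waveset.n_waves):
        members = set(waveset.members(w))
        overlaps = {p: len(members & truth.wave_members(genotype, p))
                    for p in range(truth.config.n_waves)}
        mapping[w] = max(overlaps, key=lambda p: (overlaps[p], -p))
    return mapping


def dynamic_call_metrics(calls: pd.DataFrame, truth: SyntheticTruth,
                         genotype: str) -> tuple[float, float]:
    """(sensitivity, specificity) of the dynamic flags against the truth."""
    called = set(calls.index[calls["dynamic"]])
    planted = truth.dynamic_features(genotype)
    universe = set(calls.index)
    tp = len(called & planted)
    tn = len((universe - called) & (universe - planted))
    sens = tp / len(planted) if planted else float("nan")
    spec = tn / len(universe - planted) if universe - planted else float("nan")
    return sens, spec


def wave_ari(waveset, truth: SyntheticTruth, genotype: str) -> float:
    """Adjusted Rand index between fitted assignment and planted waves,
    over the planted dynamic features (unassigned = its own label)."""
    planted = sorted(truth.dynamic_features(genotype))
    truth_labels = [truth.wave_assignment[genotype][f] for f in planted]
    fitted = waveset.assignment.reindex(planted).fillna(-1).astype(int)
    return float(adjusted_rand_score(truth_labels, fitted.to_numpy()))


def flow_edge_f1(flow, wt_waveset, onc_waveset, truth: SyntheticTruth
                 ) -> tuple[float, float, float]:
    """(precision, recall, F1) of called flow edges against planted edges,
    after matching fitted waves to planted waves by member overlap."""
    wt_map = _map_fitted_to_planted(wt_waveset, truth, "WT")
    onc_map = _map_fitted_to_planted(onc_waveset, truth, "Onc")
    called = set()
    for u, v in flow.graph.edges():
        wu = flow.graph.nodes[u]["wave"]
        wv = flow.graph.nodes[v]["wave"]
        called.add((wt_map[wu], onc_map[wv]))
    planted = {(a, b) for a, b, _ in truth.flow_edges}
    if not called and not planted:
        return 1.0, 1.0, 1.0
    tp = len(called & planted)
    prec = tp / len(called) if called else 0.0
    rec = tp / len(planted) if planted else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def hub_metrics(networks, truth: SyntheticTruth, genotype: str
                ) -> tuple[float, float]:
    """(recall, precision) of pooled called hubs against planted hub blocks."""
    called: set[str] = set()
    for nw in networks:
        called |= nw.hub_features()
    planted = truth.all_hubs(genotype)
    if not planted:
        return float("nan"), float("nan")
    recall = len(called & planted) / len(planted)
    precision = len(called & planted) / len(called) if called else 0.0
    return recall, precision


def typing_accuracy(typing: pd.DataFrame, truth: SyntheticTruth) -> float:
    """Fraction of scorable signatures whose called type matches the truth."""
    scored = [s for s in typing.index if s in truth.signature_types]
    if not scored:
        return float("nan")
    hits = sum(int(typing.loc[s, "type"]) == truth.signature_types[s]
               for s in scored)
    return hits / len(scored)


def benchmark_recovery(truth: SyntheticTruth, *,
                       calls: dict[str, pd.DataFrame] | None = None,
                       wavesets: dict[str, object] | None = None,
                       flow=None,
                       networks: dict[str, list] | None = None,
                       typing: dict[str, pd.DataFrame] | None = None
                       ) -> pd.DataFrame:
    """Recovery report over whatever pipeline outputs are supplied.

    Returns a tidy frame (metric, genotype, value); all values lie in [0, 1].
    """
    rows = []
    if calls:
        for g, table in calls.items():
            if not set(table.index) == set(truth.features):
                raise ValueError("call table feature universe does not match truth")
            sens, spec = dynamic_call_metrics(table, truth, g)
            rows.append(("dynamic_sensitivity", g, sens))
            rows.append(("dynamic_specificity", g, spec))
    if wavesets:
        for g, ws in wavesets.items():
            rows.append(("wave_ari", g, wave_ari(ws, truth, g)))
    if flow is not None and wavesets:
        prec, rec, f1 = flow_edge_f1(flow, wavesets["WT"], wavesets["Onc"], truth)
        rows.append(("flow_edge_precision", "both", prec))
        rows.append(("flow_edge_recall", "both", rec))
        rows.append(("flow_edge_f1", "both", f1))
    if networks:
        for g, nws in networks.items():
            recall, precision = hub_metrics(nws, truth, g)
            rows.append(("hub_recall", g, recall))
            rows.append(("hub_precision", g, precision))
    if typing:
        for g, table in typing.items():
            rows.append(("type_accuracy", g, typing_accuracy(table, truth)))
    return pd.DataFrame(rows, columns=["metric", "genotype", "value"])
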