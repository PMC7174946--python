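"""Synthetic five-arm multi-omic study generator with planted ground truth.

Emulates the structure of the sequencing study this pipeline targets —
five groups (normal control NC, untreated diabetic DM, and three
treatment arms SP, FJG, SP-FJG), four RNA categories (mRNA, ncRNA,
circRNA, miRNA) — without any download. Counts are negative binomial
around gene-wise lognormal baselines; differential features shift the
diseased groups by a planted log2 fold change; drug-efficacy features
are restored to the control mean in their responsive treatment arms;
planted miRNA→target pairs carry opposed trend signs and exact seed
sites in generated sequences. Every planting is recorded in a
:class:`TruthBundle` so downstream stages can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from . import reference
from .cerna import SITE_SCORES, _revcomp, scan_sites

GROUPS = reference.GROUPS
TREATMENTS = reference.TREATMENTS
CATEGORIES = ("mRNA", "ncRNA", "circRNA", "miRNA")
CATEGORY_PREFIX = {"mRNA": "mRNA:", "ncRNA": "nc:", "circRNA": "circ:", "miRNA": "miR:"}

#: Comparisons screened by the study: disease vs control, each arm vs both.
COMPARISONS = [
    ("DM", "NC"), ("SP", "DM"), ("FJG", "DM"), ("SP-FJG", "DM"),
    ("SP", "NC"), ("FJG", "NC"), ("SP-FJG", "NC"),
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SimulationConfig:
    """Desk-scale defaults for the multi-omic generator.

    ``n_features`` sets matrix sizes per category (study-scale runs use
    larger values via config); ``de_fraction`` of each category is
    differential between DM and NC at ±``log2fc``; ``efficacy_fraction``
    of those is restored by treatment. ``dispersion`` is the NB
    overdispersion (var = μ + φμ²); ``libsize_sigma`` the lognormal
    spread of per-sample size factors.
    """

    n_features: dict = field(default_factory=lambda: {
        "mRNA": 1200, "ncRNA": 250, "circRNA": 250, "miRNA": 180})
    de_fraction: float = 0.1
    log2fc: float = 2.0
    dispersion: float = 0.1
    efficacy_fraction: float = 0.6
    all_treatment_prob: float = 0.5
    n_target_pairs: int = 30
    libsize_sigma: float = 0.2
    baseline_log_mean: float = 5.0
    baseline_log_sigma: float = 1.5
    coexpr_blocks: dict = field(default_factory=dict)  # label -> (category, size)
    coexpr_strength: float = 0.0

    def __post_init__(self):
        for name in ("de_fraction", "efficacy_fraction", "all_treatment_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        unknown = set(self.n_features) - set(CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown categories in n_features: {sorted(unknown)}")


@dataclass
class TruthBundle:
    """Planted ground truth for one simulated study.

    ``de_features`` maps comparison label → {(feature, direction)};
    ``efficacy_features`` maps treatment → restored feature set;
    ``target_pairs`` holds (miRNA, target, site class); ``triads`` the
    planted (miRNA, mRNA, sponge) ceRNA units; ``modules`` feature →
    coexpression block label; ``hub_nodes`` the planted PPI hubs.
    """

    de_features: dict = field(default_factory=dict)
    efficacy_features: dict = field(default_factory=dict)
    target_pairs: list = field(default_factory=list)
    triads: list = field(default_factory=list)
    modules: dict = field(default_factory=dict)
    hub_nodes: list = field(default_factory=list)
    enriched_sets: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["de_features"] = {
            comp: sorted(map(list, pairs)) for comp, pairs in self.de_features.items()
        }
        payload["efficacy_features"] = {
            t: sorted(feats) for t, feats in self.efficacy_features.items()
        }
        payload["target_pairs"] = sorted(map(list, self.target_pairs))
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def generate_design(n_per_group: int, seed: int = 0) -> pd.DataFrame:
    """Balanced five-group design table (sample_id, group, replicate)."""
    if n_per_group < 2:
        raise ConfigError("need at least 2 replicates per group")
    rows = [
        {"sample_id": f"{group}_{rep}", "group": group, "replicate": rep}
        for group in GROUPS
        for rep in range(1, n_per_group + 1)
    ]
    return pd.DataFrame(rows)


def _feature_ids(category: str, n: int) -> list[str]:
    return [f"{CATEGORY_PREFIX[category]}{i:05d}" for i in range(1, n + 1)]


def generate_multiomics(
    design: pd.DataFrame,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], TruthBundle]:
    """Four count matrices plus the TruthBundle of all plantings.

    Differential features displace the DM mean by ±log2fc relative to
    NC; efficacy features are restored to the NC mean in their
    responsive treatment arms while the others keep the DM displacement
    in every diseased arm. miRNA→target plantings pair an efficacy
    miRNA with one mRNA and one sponge of the opposite direction and
    the same responsive arms, giving noise-free sign opposition.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    samples = list(design["sample_id"])
    groups = list(design["group"])
    size_factors = np.exp(rng.normal(0.0, config.libsize_sigma, size=len(samples)))

    truth = TruthBundle()
    for t_arm, r_arm in COMPARISONS:
        truth.de_features[f"{t_arm} vs {r_arm}"] = set()
    for treatment in TREATMENTS:
        truth.efficacy_features[treatment] = set()

    matrices: dict[str, pd.DataFrame] = {}
    feature_meta: dict[str, dict] = {}  # feature -> dict(direction, arms or None)
    for category in CATEGORIES:
        n_feat = int(config.n_features.get(category, 0))
        feats = _feature_ids(category, n_feat)
        base_mu = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sigma, n_feat))
        n_de = int(round(config.de_fraction * n_feat))
        de_idx = rng.choice(n_feat, size=n_de, replace=False) if n_de else np.array([], dtype=int)
        directions = rng.choice([1, -1], size=n_de)
        n_eff = int(round(config.efficacy_fraction * n_de))
        eff_mask = np.zeros(n_de, dtype=bool)
        if n_eff:
            eff_mask[rng.choice(n_de, size=n_eff, replace=False)] = True

        # per-feature log2 offset by group
        offsets = np.zeros((n_feat, len(GROUPS)))
        gidx = {g: i for i, g in enumerate(GROUPS)}
        for j, (fi, direction) in enumerate(zip(de_idx, directions)):
            feature = feats[fi]
            shift = direction * config.log2fc
            offsets[fi, gidx["DM"]] = shift
            if eff_mask[j]:
                if rng.random() < config.all_treatment_prob:
                    arms = set(TREATMENTS)
                else:
                    n_arms = rng.integers(1, 3)
                    arms = set(rng.choice(TREATMENTS, size=n_arms, replace=False))
                for treatment in TREATMENTS:
                    offsets[fi, gidx[treatment]] = 0.0 if treatment in arms else shift
                for treatment in arms:
                    truth.efficacy_features[treatment].add(feature)
                feature_meta[feature] = {"direction": int(direction), "arms": arms,
                                         "category": category}
            else:
                for treatment in TREATMENTS:
                    offsets[fi, gidx[treatment]] = shift
                feature_meta[feature] = {"direction": int(direction), "arms": set(),
                                         "category": category}

        for t_arm, r_arm in COMPARISONS:
            comp = f"{t_arm} vs {r_arm}"
            delta = offsets[:, gidx[t_arm]] - offsets[:, gidx[r_arm]]
            for fi in np.nonzero(delta)[0]:
                truth.de_features[comp].add((feats[fi], "up" if delta[fi] > 0 else "down"))

        # optional shared latent factors for coexpression blocks
        block_effect = np.zeros((n_feat, len(samples)))
        for label, (block_cat, size) in config.coexpr_blocks.items():
            if block_cat != category:
                continue
            free = [i for i in range(n_feat) if feats[i] not in truth.modules
                    and i not in de_idx]
            chosen = rng.choice(free, size=int(size), replace=False)
            latent = rng.normal(0.0, 1.0, size=len(samples))
            for fi in chosen:
                truth.modules[feats[fi]] = label
                block_effect[fi] = config.coexpr_strength * latent

        group_cols = np.array([gidx[g] for g in groups])
        mu = (
            base_mu[:, None]
            * np.power(2.0, offsets[:, group_cols] + block_effect)
            * size_factors[None, :]
        )
        counts = _nb_counts(rng, mu, config.dispersion)
        matrices[category] = pd.DataFrame(counts, index=feats, columns=samples)

    _plant_target_pairs(rng, config, truth, feature_meta)
    return matrices, truth


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _plant_target_pairs(rng, config, truth: TruthBundle, feature_meta: dict) -> None:
    """Pair efficacy miRNAs with opposite-direction mRNA and sponge features."""
    def pool(category, direction):
        return sorted(
            f for f, meta in feature_meta.items()
            if meta["category"] == category and meta["direction"] == direction
            and meta["arms"]
        )

    mirnas = sorted(f for f, m in feature_meta.items() if m["category"] == "miRNA" and m["arms"])
    rng.shuffle(mirnas)
    used_targets: set = set()
    site_classes = list(SITE_SCORES)
    for mir in mirnas:
        if len(truth.triads) >= config.n_target_pairs:
            break
        direction = feature_meta[mir]["direction"]
        arms = feature_meta[mir]["arms"]
        mrna_pool = [f for f in pool("mRNA", -direction)
                     if f not in used_targets and feature_meta[f]["arms"] == arms]
        sponge_pool = [f for f in pool("circRNA", -direction) + pool("ncRNA", -direction)
                       if f not in used_targets and feature_meta[f]["arms"] == arms]
        if not mrna_pool or not sponge_pool:
            continue
        mrna = mrna_pool[rng.integers(len(mrna_pool))]
        sponge = sponge_pool[rng.integers(len(sponge_pool))]
        used_targets.update({mrna, sponge})
        cls_m = site_classes[rng.integers(len(site_classes))]
        cls_s = site_classes[rng.integers(len(site_classes))]
        truth.target_pairs.append((mir, mrna, cls_m))
        truth.target_pairs.append((mir, sponge, cls_s))
        truth.triads.append({"mirna": mir, "mrna": mrna, "sponge": sponge})


def generate_annotations(
    features,
    n_sets: int,
    seed: int = 0,
    de_features=None,
    enriched_fraction: float = 0.8,
    set_size: int = 25,
) -> tuple[dict[str, set], list[tuple], dict]:
    """Gene-set collection (GMT-style), term DAG and enriched-set truth.

    Random sets of ~``set_size`` genes; when ``de_features`` is given,
    one additional set is deliberately over-represented: it draws
    ``enriched_fraction`` of its members from the differential list.
    The DAG is a random tree over the set ids (acyclic by construction).
    """
    features = list(features)
    if not features:
        raise ConfigError("feature list is empty")
    if n_sets < 1:
        raise ConfigError("need at least one gene set")
    rng = np.random.default_rng(seed)
    gene_sets: dict[str, set] = {}
    for i in range(n_sets):
        size = min(len(features), set_size)
        members = rng.choice(features, size=size, replace=False)
        gene_sets[f"SET{i + 1:03d}"] = set(members)
    truth = {"enriched": []}
    if de_features:
        de_list = [f for f in de_features if f in set(features)]
        n_from_de = min(len(de_list), int(round(enriched_fraction * set_size)))
        background = [f for f in features if f not in set(de_list)]
        n_bg = min(len(background), set_size - n_from_de)
        members = set(rng.choice(de_list, size=n_from_de, replace=False))
        if n_bg:
            members |= set(rng.choice(background, size=n_bg, replace=False))
        set_id = f"SET{n_sets + 1:03d}_planted"
        gene_sets[set_id] = members
        truth["enriched"].append(set_id)
    ids = sorted(gene_sets)
    dag_edges = [(ids[int(rng.integers(i))], ids[i]) for i in range(1, len(ids))]
    return gene_sets, dag_edges, truth


_BASES = "ACGT"


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _site_string(rng, mirna: str, site_class: str) -> str:
    mir = mirna.replace("U", "T")
    if site_class == "8mer":
        return _revcomp(mir[1:8]) + "A"
    if site_class == "7mer-m8":
        non_a = "CGT"[rng.integers(3)]
        return _revcomp(mir[1:8]) + non_a
    if site_class == "7mer-A1":
        return _revcomp(mir[1:7]) + "A"
    raise ConfigError(f"unknown site class {site_class!r}")


def _has_any_site(mirnas: dict[str, str], seq: str) -> bool:
    return any(scan_sites(m_seq, seq, m_id, "x") for m_id, m_seq in mirnas.items())


def generate_sequences(
    target_pairs,
    seed: int = 0,
    n_decoys: int = 0,
    mirna_length: int = 22,
    utr_length: int = 120,
) -> tuple[dict[str, str], dict[str, str]]:
    """Mature miRNA and target-UTR sequences realizing the planted sites.

    Each planted (miRNA, target, class) pair gets exactly the recorded
    site class embedded in the target UTR; decoy UTRs are redrawn until
    an exhaustive scan finds no site for any emitted miRNA. Sequences
    are deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    mirnas: dict[str, str] = {}
    targets_sites: dict[str, list] = {}
    for mir, target, site_class in target_pairs:
        if mir not in mirnas:
            mirnas[mir] = _random_seq(rng, mirna_length).replace("T", "U")
        targets_sites.setdefault(target, []).append((mir, site_class))

    utrs: dict[str, str] = {}
    for target, plants in targets_sites.items():
        for _ in range(200):
            seq = list(_random_seq(rng, utr_length))
            span = utr_length // max(1, len(plants))
            ok = True
            for i, (mir, site_class) in enumerate(plants):
                site = _site_string(rng, mirnas[mir], site_class)
                lo = i * span
                hi = min(utr_length - len(site), (i + 1) * span - len(site))
                if hi < lo:
                    ok = False
                    break
                pos = int(rng.integers(lo, hi + 1))
                seq[pos : pos + len(site)] = site
            if not ok:
                continue
            seq = "".join(seq)
            found = {
                (s["mirna"], s["site_class"])
                for m_id, m_seq in mirnas.items()
                for s in scan_sites(m_seq, seq, m_id, target)
            }
            if found == {(mir, cls) for mir, cls in plants}:
                utrs[target] = seq
                break
        else:
            raise RuntimeError(f"could not realize planted sites for {target}")

    for i in range(n_decoys):
        name = f"decoy:{i + 1:04d}"
        for _ in range(500):
            seq = _random_seq(rng, utr_length)
            if not _has_any_site(mirnas, seq):
                utrs[name] = seq
                break
        else:
            raise RuntimeError("could not generate a site-free decoy UTR")
    return mirnas, utrs


def generate_ppi(
    features,
    model: str = "barabasi_albert",
    seed: int = 0,
    attach: int = 3,
    edge_prob: float = 0.02,
    n_hubs: int = 10,
) -> tuple[pd.DataFrame, list]:
    """Scored undirected PPI edge list plus top-degree hub truth.

    ``barabasi_albert`` (preferential attachment, heavy-tailed degrees)
    or ``erdos_renyi``. Hub truth is the ``n_hubs`` highest-degree
    nodes, degree descending with id tie-break.
    """
    features = list(features)
    if len(features) < 10:
        raise ConfigError("need at least 10 features for a PPI graph")
    if model == "barabasi_albert":
        graph = nx.barabasi_albert_graph(len(features), attach, seed=seed)
    elif model == "erdos_renyi":
        graph = nx.gnp_random_graph(len(features), edge_prob, seed=seed)
    else:
        raise ConfigError(f"unknown PPI model {model!r}")
    mapping = dict(enumerate(features))
    graph = nx.relabel_nodes(graph, mapping)
    rng = np.random.default_rng(seed)
    rows = [
        {"node1": u, "node2": v, "score": round(float(rng.uniform(0.4, 1.0)), 3)}
        for u, v in graph.edges()
    ]
    edges = pd.DataFrame(rows, columns=["node1", "node2", "score"])
    ranked = sorted(graph.degree(), key=lambda nd: (-nd[1], nd[0]))
    hubs = [n for n, _ in ranked[:n_hubs]]
    return edges, hubs


def generate_phenotypes(
    design: pd.DataFrame,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Tidy per-animal phenotype table at the published operating point.

    Draws every variable from Normal(printed group mean, printed SD ×
    ``noise_scale``), truncated at 0.01. Glucose-tolerance rows carry
    ``time_min``; scalar panels leave it empty. ``noise_scale=0``
    reproduces the group means exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def draw(mean, sd):
        if noise_scale == 0 or sd == 0:
            return float(mean)
        return float(max(0.01, rng.normal(mean, sd * noise_scale)))

    for row in design.itertuples(index=False):
        for test, curves in reference.GLUCOSE_CURVES.items():
            for t, (mean, sd) in zip((0, 30, 60, 120), curves[row.group]):
                rows.append({"sample_id": row.sample_id, "group": row.group,
                             "variable": test, "time_min": t, "value": draw(mean, sd)})
        scalars = {"FBG": reference.FBG_WEEK6[row.group], "FINS": reference.FINS[row.group]}
        for name, by_group in reference.SERUM.items():
            scalars[name] = by_group[row.group]
        for name, (mean, sd) in scalars.items():
            rows.append({"sample_id": row.sample_id, "group": row.group,
                         "variable": name, "time_min": None, "value": draw(mean, sd)})
    return pd.DataFrame(rows, columns=["sample_id", "group", "variable", "time_min", "value"])


def generate_block_expression(
    block_sizes: dict[str, int],
    n_noise: int,
    n_samples: int,
    within_cor: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian expression with equicorrelated planted blocks.

    Each block feature is √ρ·latent + √(1−ρ)·noise so the expected
    within-block Pearson correlation is ``within_cor``; the ``n_noise``
    background features are independent. Returns (features × samples,
    truth labels with "grey" for background).
    """
    if not 0 <= within_cor < 1:
        raise ConfigError("within_cor must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows, labels, index = [], [], []
    for label, size in block_sizes.items():
        latent = rng.normal(size=n_samples)
        for i in range(size):
            eps = rng.normal(size=n_samples)
            rows.append(np.sqrt(within_cor) * latent + np.sqrt(1 - within_cor) * eps)
            labels.append(label)
            index.append(f"{label}:{i + 1:03d}")
    for i in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        labels.append(GREY_LABEL)
        index.append(f"noise:{i + 1:03d}")
    expr = pd.DataFrame(rows, index=index, columns=[f"s{j + 1}" for j in range(n_samples)])
    return expr, pd.Series(labels, index=index, name="module")


GREY_LABEL = "grey"
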