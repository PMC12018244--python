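"""EPIC-like paired methylation experiments with known ground truth.

The generator emulates the study design the pipeline targets: a small number
of independent paired experiments (groups), each one treated sample and one
control sample from the same donor pool, where between-pool (subject)
variation dominates the treatment effect, and a chosen number of probes per
group carry planted hypo-/hyper-methylation of fixed beta-scale size.

Betas are built on the logit scale — probe baseline + per-(group, probe)
subject shift + treatment offset + independent noise, then inverse-logit —
so every generated value lies strictly inside (0, 1).  The treatment offset
is the probe-specific logit increment that moves the pre-noise control beta
by exactly +/- ``effect_size`` on the beta scale, so planted treated-control
differences equal the requested effect before noise.

All randomness flows through an explicit mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    ISLAND_RELATIONS,
    REGION_GROUPS,
    parse_gene_region,
    parse_region_group,
)
from .preprocess import PairedDesign, SamplePair

# loosely EPIC-like marginal frequencies; exact proportions are not critical,
# only that every category occurs and open sea dominates
DEFAULT_REGION_WEIGHTS = {
    "TSS200": 0.10,
    "TSS1500": 0.13,
    "5'UTR": 0.12,
    "1stExon": 0.05,
    "Body": 0.48,
    "3'UTR": 0.07,
    "ExonBnd": 0.05,
}
DEFAULT_ISLAND_WEIGHTS = {
    "Island": 0.19,
    "N_Shore": 0.11,
    "S_Shore": 0.10,
    "N_Shelf": 0.05,
    "S_Shelf": 0.05,
    "OpenSea": 0.50,
}
#: methylation direction -> expected expression direction used by
#: simulate_expression by default; body hypo-methylation activates, promoter
#: changes follow the classical repression logic
DEFAULT_CONCORDANCE_RULE = {
    ("body", "hypo"): "up",
    ("body", "hyper"): "down",
    ("promoter", "hypo"): "down",
    ("promoter", "hyper"): "down",
}

_DIRECTIONS = ("hypo", "hyper")


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _check_weights(weights: Mapping[str, float], vocab: frozenset, what: str) -> None:
    unknown = set(weights) - vocab
    if unknown:
        raise ValueError(f"unknown {what} categories: {sorted(unknown)}")
    total = sum(weights.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"{what} weights must sum to 1 (got {total})")
    if any(w < 0 for w in weights.values()):
        raise ValueError(f"{what} weights must be non-negative")


def make_manifest(
    n_probes: int,
    n_genes: int,
    region_weights: Mapping[str, float] | None = None,
    island_weights: Mapping[str, float] | None = None,
    seed: int = 0,
    sex_fraction: float = 0.02,
) -> pd.DataFrame:
    """Synthetic probe-annotation manifest.

    Each probe gets a chromosome (a ``sex_fraction`` share on X/Y), zero or
    more ``GENE:RegionGroup`` annotations and one island relation.
    Deterministic for a fixed seed.
    """
    if n_probes < 1 or n_genes < 1:
        raise ValueError("n_probes and n_genes must be positive")
    if n_genes > n_probes:
        raise ValueError("n_genes must not exceed n_probes")
    region_weights = dict(region_weights or DEFAULT_REGION_WEIGHTS)
    island_weights = dict(island_weights or DEFAULT_ISLAND_WEIGHTS)
    _check_weights(region_weights, REGION_GROUPS, "region group")
    _check_weights(island_weights, ISLAND_RELATIONS, "island relation")

    rng = np.random.default_rng(seed)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    genes = [f"GENE{i:05d}" for i in range(n_genes)]

    autosomes = [str(c) for c in range(1, 23)]
    chroms = rng.choice(autosomes, size=n_probes)
    sex_mask = rng.random(n_probes) < sex_fraction
    chroms[sex_mask] = rng.choice(["X", "Y"], size=int(sex_mask.sum()))

    # 0..3 gene annotations per probe; most probes genic with one annotation
    n_annot = rng.choice([0, 1, 2, 3], size=n_probes, p=[0.22, 0.60, 0.14, 0.04])
    region_names = list(region_weights)
    region_p = np.array([region_weights[r] for r in region_names])
    island_names = list(island_weights)
    island_p = np.array([island_weights[r] for r in island_names])

    gene_region = []
    for k in n_annot:
        if k == 0:
            gene_region.append("")
            continue
        gs = rng.choice(genes, size=k, replace=False if k <= n_genes else True)
        rs = rng.choice(region_names, size=k, p=region_p)
        gene_region.append(";".join(f"{g}:{r}" for g, r in zip(gs, rs)))

    return pd.DataFrame(
        {
            "chromosome": chroms,
            "gene_region": gene_region,
            "island_relation": rng.choice(island_names, size=n_probes, p=island_p),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study.

    ``probe_truth`` holds one row per (probe, group) with the planted
    beta-scale delta (exactly 0 for null probes) and a direction label
    consistent with its sign.  ``gene_truth`` projects planted probes onto
    (gene, region class, methylation direction) via the manifest.
    ``expression_direction`` is filled by :func:`simulate_expression`.
    """

    probe_truth: pd.DataFrame  # probe_id, group, delta_beta, direction
    gene_truth: pd.DataFrame  # gene, region_class, meth_direction
    all_genes: list[str]
    expression_direction: pd.Series | None = None

    def planted_probes(self, group: str, direction: str | None = None) -> set[str]:
        pt = self.probe_truth
        mask = (pt["group"] == group) & (pt["direction"] != "null")
        if direction is not None:
            mask &= pt["direction"] == direction
        return set(pt.loc[mask, "probe_id"])


def _draw_planted(
    rng: np.random.Generator,
    probe_ids: Sequence[str],
    group_names: Sequence[str],
    n_hypo: int,
    n_hyper: int,
    shared_fraction: float,
) -> dict[str, dict[str, list[str]]]:
    """Disjoint hypo/hyper planted sets per group, with a shared core."""
    n_groups = len(group_names)
    shared_h = int(round(shared_fraction * n_hypo))
    shared_y = int(round(shared_fraction * n_hyper))
    need = (shared_h + (n_hypo - shared_h) * n_groups) + (
        shared_y + (n_hyper - shared_y) * n_groups
    )
    if need > len(probe_ids):
        raise ValueError("planted counts exceed the number of probes available")
    pool = list(rng.permutation(np.asarray(probe_ids, dtype=object)))
    shared_hypo = pool[:shared_h]
    del pool[:shared_h]
    shared_hyper = pool[:shared_y]
    del pool[:shared_y]
    planted: dict[str, dict[str, list[str]]] = {}
    for g in group_names:
        own_h = pool[: n_hypo - shared_h]
        del pool[: n_hypo - shared_h]
        own_y = pool[: n_hyper - shared_y]
        del pool[: n_hyper - shared_y]
        planted[g] = {
            "hypo": list(shared_hypo) + own_h,
            "hyper": list(shared_hyper) + own_y,
        }
    return planted


def simulate_study(
    manifest: pd.DataFrame,
    groups: int | Sequence[str] = ("a", "b", "c"),
    n_planted_hypo: int = 50,
    n_planted_hyper: int = 50,
    effect_size: float = 0.3,
    subject_shift_sd: float = 1.5,
    noise_sd: float = 0.1,
    shared_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, PairedDesign, SimulationTruth]:
    """Simulate paired treated/control beta matrices over a manifest.

    Parameters mirror the emulated study: few groups, one pair each, subject
    shift (logit sd) well above the noise so samples cluster by group, and
    planted effects of ``effect_size`` on the beta scale applied to the
    treated sample only.  ``shared_fraction`` of each group's planted probes
    come from a core common to all groups, so downstream multi-group
    intersections are non-trivial.
    """
    if effect_size <= 0 or effect_size >= 1:
        raise ValueError("effect_size must lie in (0, 1)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if subject_shift_sd <= 0:
        raise ValueError("subject_shift_sd must be positive")
    if n_planted_hypo < 0 or n_planted_hyper < 0:
        raise ValueError("planted counts must be non-negative")
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must lie in [0, 1]")
    group_names = (
        [chr(ord("a") + i) for i in range(groups)] if isinstance(groups, int) else list(groups)
    )
    rng = np.random.default_rng(seed)
    probe_ids = list(manifest.index)
    n = len(probe_ids)

    planted = _draw_planted(
        rng, probe_ids, group_names, n_planted_hypo, n_planted_hyper, shared_fraction
    )

    # bimodal probe baseline on the logit scale (typical array beta landscape)
    comp = rng.choice([0, 1, 2], size=n, p=[0.42, 0.42, 0.16])
    base_logit = np.where(
        comp == 0,
        rng.normal(-2.2, 0.8, n),
        np.where(comp == 1, rng.normal(2.2, 0.8, n), rng.normal(0.0, 0.9, n)),
    )
    base_beta = _invlogit(base_logit)

    idx = {p: i for i, p in enumerate(probe_ids)}
    margin = 0.02
    betas: dict[str, np.ndarray] = {}
    pairs = []
    truth_rows = []
    for g in group_names:
        shift = rng.normal(0.0, subject_shift_sd, n)
        control_pre = _invlogit(base_logit + shift)
        treated_pre = control_pre.copy()
        delta = np.zeros(n)
        for direction, sign in (("hypo", -1.0), ("hyper", +1.0)):
            rows = np.array([idx[p] for p in planted[g][direction]], dtype=int)
            if rows.size == 0:
                continue
            lo = effect_size + margin if sign < 0 else margin
            hi = 1.0 - margin if sign < 0 else 1.0 - effect_size - margin
            control_pre[rows] = np.clip(control_pre[rows], lo, hi)
            treated_pre[rows] = control_pre[rows] + sign * effect_size
            delta[rows] = sign * effect_size
        treated = _invlogit(_logit(treated_pre) + rng.normal(0.0, noise_sd, n))
        control = _invlogit(_logit(control_pre) + rng.normal(0.0, noise_sd, n))
        t_id, c_id = f"EVs_{g}", f"Ctrl_{g}"
        betas[t_id] = treated
        betas[c_id] = control
        pairs.append(SamplePair(name=g, treated=t_id, control=c_id))
        truth_rows.append(
            pd.DataFrame(
                {
                    "probe_id": probe_ids,
                    "group": g,
                    "delta_beta": delta,
                    "direction": np.where(
                        delta < 0, "hypo", np.where(delta > 0, "hyper", "null")
                    ),
                }
            )
        )
    beta = pd.DataFrame(betas, index=pd.Index(probe_ids, name="probe_id"))
    design = PairedDesign(groups=tuple(pairs))

    gene_rows = []
    for g in group_names:
        for direction in _DIRECTIONS:
            for p in planted[g][direction]:
                for gene, region in parse_gene_region(manifest.at[p, "gene_region"]):
                    gene_rows.append((gene, parse_region_group(region), direction))
    gene_truth = (
        pd.DataFrame(gene_rows, columns=["gene", "region_class", "meth_direction"])
        .drop_duplicates()
        .sort_values(["gene", "region_class", "meth_direction"], ignore_index=True)
        if gene_rows
        else pd.DataFrame(columns=["gene", "region_class", "meth_direction"])
    )
    all_genes = sorted(
        {
            gene
            for field in manifest["gene_region"]
            for gene, _ in parse_gene_region(field)
        }
    )
    truth = SimulationTruth(
        probe_truth=pd.concat(truth_rows, ignore_index=True),
        gene_truth=gene_truth,
        all_genes=all_genes,
    )
    return beta, design, truth


def simulate_expression(
    truth: SimulationTruth,
    concordance_rule: Mapping[tuple[str, str], str] | None = None,
    flip_fraction: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Differential-expression table matched to a simulated methylation truth.

    Genes carrying planted methylation get the direction the rule assigns to
    their (region class, methylation direction), inverted with probability
    ``flip_fraction``, and an adjusted p below ``alpha``; all other manifest
    genes draw adjusted p at or above ``alpha``.  Genes whose combination is
    absent from the rule stay null.  A gene with several planted
    combinations uses its lexicographically first one.
    """
    if not 0 <= flip_fraction <= 1:
        raise ValueError("flip_fraction must lie in [0, 1]")
    rule = dict(DEFAULT_CONCORDANCE_RULE if concordance_rule is None else concordance_rule)
    for (region_class, meth_dir), expr_dir in rule.items():
        if region_class not in {"promoter", "body"}:
            raise ValueError(f"unknown region_class {region_class!r} in rule")
        if meth_dir not in _DIRECTIONS:
            raise ValueError(f"unknown methylation direction {meth_dir!r} in rule")
        if expr_dir not in {"up", "down"}:
            raise ValueError(f"unknown expression direction {expr_dir!r} in rule")

    rng = np.random.default_rng(seed)
    first = truth.gene_truth.drop_duplicates("gene", keep="first")
    rows = []
    signif_genes = set()
    for rec in first.itertuples(index=False):
        direction = rule.get((rec.region_class, rec.meth_direction))
        if direction is None:
            continue
        if rng.random() < flip_fraction:
            direction = "down" if direction == "up" else "up"
        rows.append((rec.gene, direction, float(rng.uniform(0, alpha))))
        signif_genes.add(rec.gene)
    for gene in truth.all_genes:
        if gene in signif_genes:
            continue
        rows.append(
            (gene, rng.choice(["up", "down"]), float(rng.uniform(alpha, 1.0)))
        )
    degs = pd.DataFrame(rows, columns=["gene", "direction", "adj_p"])
    truth.expression_direction = degs.set_index("gene")["direction"].where(
        degs.set_index("gene")["adj_p"] < alpha
    )
    return degs.sort_values("gene", ignore_index=True)
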