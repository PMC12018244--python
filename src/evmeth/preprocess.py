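"""Beta/M-value computation, probe filtering, variable-probe selection, PCA.

The pipeline's substrate is a beta-value matrix (probes x samples,
methylation fractions in [0, 1]) assumed already normalized.  This module
supplies the standard Infinium transformations (beta from intensities with
the +100 offset convention, the logit2 M-value), the usual probe exclusions
(detection p-value, SNP-overlapping probes, sex chromosomes, cross-reactive
probes), a coefficient-of-variation style variable-probe screen
(sd / |mean| > threshold), and sample-relationship PCA on M-values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

#: order in which filter rules are applied; a probe removed by an earlier
#: rule is attributed to it alone (first-rule-wins tallies)
FILTER_RULE_ORDER = ("detection_p", "snp", "sex_chromosome", "cross_reactive")


@dataclass(frozen=True)
class SamplePair:
    """One paired experiment: a treated and a control sample."""

    name: str
    treated: str
    control: str


@dataclass(frozen=True)
class PairedDesign:
    """Ordered collection of treated/control pairs, one per group.

    The study design this mirrors runs independent paired experiments on
    distinct donor pools; every per-group statistic downstream is computed
    from the group's own pair only.
    """

    groups: tuple[SamplePair, ...]

    def __post_init__(self) -> None:
        ids = [s for g in self.groups for s in (g.treated, g.control)]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids in a design must be distinct")
        names = [g.name for g in self.groups]
        if len(names) != len(set(names)):
            raise ValueError("group names must be distinct")

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def sample_ids(self) -> list[str]:
        return [s for g in self.groups for s in (g.treated, g.control)]

    def validate_against(self, beta: pd.DataFrame) -> None:
        missing = set(self.sample_ids) - set(beta.columns)
        if missing:
            raise ValueError(f"design samples missing from matrix: {sorted(missing)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PairedDesign":
        return cls(
            groups=tuple(
                SamplePair(g["name"], g["treated"], g["control"]) for g in d["groups"]
            )
        )

    def to_dict(self) -> dict:
        return {
            "groups": [
                {"name": g.name, "treated": g.treated, "control": g.control}
                for g in self.groups
            ]
        }

    @classmethod
    def from_json(cls, path) -> "PairedDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def compute_beta(
    meth_intensity, unmeth_intensity, offset: float = 100.0
):
    """Beta-value from methylated/unmethylated intensities.

    beta = M / (M + U + offset), the Infinium convention; the offset
    regularizes low-signal probes toward 0.  Accepts aligned arrays or
    DataFrames and preserves labels.
    """
    meth = np.asarray(meth_intensity, dtype=float)
    unmeth = np.asarray(unmeth_intensity, dtype=float)
    if meth.shape != unmeth.shape:
        raise ValueError(f"shape mismatch: {meth.shape} vs {unmeth.shape}")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if (meth < 0).any() or (unmeth < 0).any():
        raise ValueError("intensities must be non-negative")
    denom = meth + unmeth + offset
    with np.errstate(invalid="ignore"):
        beta = np.where(denom > 0, meth / np.where(denom > 0, denom, 1.0), 0.0)
    if isinstance(meth_intensity, pd.DataFrame):
        return pd.DataFrame(
            beta, index=meth_intensity.index, columns=meth_intensity.columns
        )
    return beta


def beta_to_m(beta, epsilon: float = 1e-6):
    """M-value: log2(beta / (1 - beta)) after clipping beta into [eps, 1-eps].

    The clip keeps the transform finite at fully (un)methylated probes.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    arr = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    m = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


@dataclass
class FilterReport:
    """Per-rule removal tally; removals + survivors == input probes."""

    n_input: int
    n_survivors: int
    removed: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_survivors": self.n_survivors,
            "removed": dict(self.removed),
        }


def filter_probes(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    snp_blacklist: Iterable[str] = (),
    crossreactive_blacklist: Iterable[str] = (),
    detection_p: pd.DataFrame | None = None,
    detection_p_max: float = 0.01,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop unreliable probes from a beta matrix.

    Rules, applied in order with first-rule-wins attribution:
    detection p-value above ``detection_p_max`` in any sample; membership in
    the SNP blacklist; manifest chromosome X or Y; membership in the
    cross-reactive blacklist.
    """
    missing = set(beta.index) - set(manifest.index)
    if missing:
        raise ValueError(
            f"{len(missing)} probe(s) in matrix absent from manifest, e.g. "
            f"{sorted(missing)[:5]}"
        )
    snp = set(snp_blacklist)
    xreact = set(crossreactive_blacklist)
    chrom = manifest.loc[beta.index, "chromosome"].astype(str)
    on_sex = chrom.str.upper().str.lstrip("CHR").isin({"X", "Y"})

    if detection_p is not None:
        detp = detection_p.reindex(index=beta.index, columns=beta.columns)
        if detp.isna().any().any():
            raise ValueError("detection_p matrix is not aligned with beta")
        fails_det = (detp > detection_p_max).any(axis=1)
    else:
        fails_det = pd.Series(False, index=beta.index)

    removed = {rule: 0 for rule in FILTER_RULE_ORDER}
    keep = []
    for probe in beta.index:
        if fails_det[probe]:
            removed["detection_p"] += 1
        elif probe in snp:
            removed["snp"] += 1
        elif on_sex[probe]:
            removed["sex_chromosome"] += 1
        elif probe in xreact:
            removed["cross_reactive"] += 1
        else:
            keep.append(probe)
    out = beta.loc[keep]
    return out, FilterReport(
        n_input=len(beta), n_survivors=len(out), removed=removed
    )


def select_variable_probes(
    m: pd.DataFrame,
    ratio_threshold: float = 0.5,
    return_info: bool = False,
):
    """Probes whose sd / |mean| across samples exceeds ``ratio_threshold``.

    Sample standard deviation (ddof=1) over the row, divided by the absolute
    row mean; the inequality is strict.  M-values are signed, so the
    denominator is |mean|; rows whose mean is below machine tolerance are
    excluded from selection (the ratio is ill-defined) and counted.

    Returns the selected probe index; with ``return_info=True`` also a dict
    with the zero-mean row count.
    """
    if m.shape[1] < 2:
        raise ValueError("at least 2 samples are required")
    if ratio_threshold < 0:
        raise ValueError("ratio_threshold must be non-negative")
    mean = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    tol = np.finfo(float).eps * 100
    defined = mean.abs() > tol
    ratio = sd[defined] / mean[defined].abs()
    selected = ratio.index[ratio > ratio_threshold]
    if return_info:
        return selected, {"n_zero_mean_excluded": int((~defined).sum())}
    return selected


@dataclass
class PCAResult:
    """Per-sample principal-component scores and explained-variance fractions."""

    scores: pd.DataFrame  # samples x components ("PC1", ...)
    explained_variance_ratio: np.ndarray

    def top_scores(self, k: int = 2) -> pd.DataFrame:
        return self.scores.iloc[:, : min(k, self.scores.shape[1])]


def run_pca(
    m: pd.DataFrame,
    probes: Sequence[str] | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of samples on M-values over the given probe subset.

    Probes are features (centered), samples are observations; at most
    n_samples - 1 components are meaningful.
    """
    if m.shape[1] < 2:
        raise ValueError("at least 2 samples are required for PCA")
    sub = m if probes is None else m.loc[list(probes)]
    x = sub.to_numpy(dtype=float).T  # samples x probes
    k_max = min(x.shape[0] - 1, x.shape[1])
    k = k_max if n_components is None else min(n_components, k_max)
    k = max(k, 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=sub.columns, columns=[f"PC{i+1}" for i in range(k)]
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
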