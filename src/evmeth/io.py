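"""Plain-text readers/writers for the pipeline's tabular formats.

All matrices travel as TSV with ``probe_id`` as the first column; the
manifest uses the semicolon ``GENE:RegionGroup`` convention; blacklists are
one probe id per line; designs are JSON.  Everything round-trips through
pandas.
"""

from __future__ import annotations

import pandas as pd

MANIFEST_COLUMNS = ["chromosome", "gene_region", "island_relation"]
DEG_COLUMNS = ["gene", "direction", "adj_p"]


def read_beta_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    if df.isna().any().any():
        raise ValueError(f"{path}: beta matrix contains missing values")
    vals = df.to_numpy()
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError(f"{path}: beta values must lie in [0, 1]")
    return df


def write_beta_tsv(beta: pd.DataFrame, path) -> None:
    beta.rename_axis("probe_id").to_csv(path, sep="\t", float_format="%.6g")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Generic probe x sample matrix (e.g. detection p-values)."""
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def read_manifest_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col="probe_id", dtype=str, keep_default_na=False
    )
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest lacks columns {sorted(missing)}")
    return df[MANIFEST_COLUMNS]


def write_manifest_tsv(manifest: pd.DataFrame, path) -> None:
    manifest.rename_axis("probe_id").to_csv(path, sep="\t")


def read_blacklist(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_deg_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: deG table lacks columns {sorted(missing)}")
    bad = set(df["direction"].unique()) - {"up", "down"}
    if bad:
        raise ValueError(f"{path}: unknown expression direction(s) {sorted(bad)}")
    if ((df["adj_p"] < 0) | (df["adj_p"] > 1)).any():
        raise ValueError(f"{path}: adjusted p-values must lie in [0, 1]")
    return df[DEG_COLUMNS]


def write_deg_tsv(degs: pd.DataFrame, path) -> None:
    degs.to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth, path) -> None:
    """Planted-effect table, one row per (probe, group)."""
    truth.probe_truth.to_csv(path, sep="\t", index=False)
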