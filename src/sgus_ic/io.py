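"""File schemas and report writers.

All tabular files are UTF-8 comma-separated with a mandatory header
row and "." decimals.  Device identifiers are canonical names
(Breezhaler, Diskus, Ellipta, Nexthaler, Spiromax, Turbohaler) and are
normalised case-insensitively on read; unknown identifiers are kept
verbatim so the tooling also works on non-default device sets.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sgus_ic.cohort import DEVICES
from sgus_ic.model import ModelSpec, PosteriorDraws, PosteriorSummary
from sgus_ic.ranking import RankingSummary

__all__ = [
    "read_scores",
    "read_demographics",
    "read_responses",
    "load_model_spec",
    "canonical_device",
    "table2_frame",
    "write_report",
]

_CANONICAL = {d.lower(): d for d in DEVICES}

SCORES_COLUMNS = ["patient_id", "device_id", "sgus_total"]
RESPONSES_COLUMNS = ["patient_id", "device_id", "item_id", "level"]


def canonical_device(device_id: str) -> str:
    return _CANONICAL.get(str(device_id).strip().lower(), str(device_id).strip())


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s) {missing}")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "device_id": str})
    _require_columns(df, SCORES_COLUMNS, f"scores file {path}")
    df["device_id"] = df["device_id"].map(canonical_device)
    df["sgus_total"] = df["sgus_total"].astype(float)
    return df[SCORES_COLUMNS + [c for c in df.columns if c not in SCORES_COLUMNS]]


def read_responses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "device_id": str, "level": str})
    _require_columns(df, RESPONSES_COLUMNS, f"responses file {path}")
    df["device_id"] = df["device_id"].map(canonical_device)
    df["item_id"] = df["item_id"].astype(int)
    return df


def read_demographics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, ["patient_id", "group"], f"demographics file {path}")
    return df


def load_model_spec(path: str | Path, **overrides) -> ModelSpec:
    """Model spec from YAML; keyword overrides win over file values."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return ModelSpec(**data)


def table2_frame(summary: PosteriorSummary, order: list[str]) -> pd.DataFrame:
    """Cross-table of the pairwise results in the published layout.

    Devices are ordered best-to-worst along the diagonal (pass the
    SUCRA order); each diagonal cell carries the device's posterior
    mean S-GUS with its CrI, the lower triangle the AMD (better-ranked
    column device minus row device) with its CrI, and the upper
    triangle the posterior probability that the row device beats the
    column device.
    """
    pct = int(round(summary.level * 100))
    idx = {d: summary.device_ids.index(d) for d in order}
    n = len(order)
    cells = [["" for _ in range(n)] for _ in range(n)]
    tbl = summary.device_table.set_index("device_id")
    for i, di in enumerate(order):
        row = tbl.loc[di]
        cells[i][i] = (
            f"{di} S-GUS = {row.mean_sgus:.1f} "
            f"{pct}% CrI ({row.cri_lower:.1f} to {row.cri_upper:.1f})"
        )
        for j, dj in enumerate(order):
            if i == j:
                continue
            a, b = idx[di], idx[dj]
            if i > j:  # lower triangle: AMD of the better-ranked (column) device
                cells[i][j] = (
                    f"AMD = {summary.amd_mean[b, a]:.2f} "
                    f"{pct}% CrI ({summary.amd_lower[b, a]:.1f} "
                    f"to {summary.amd_upper[b, a]:.1f})"
                )
            else:  # upper triangle: Post p that the row device is more usable
                cells[i][j] = f"Post p = {summary.post_p[a, b]:.3f}"
    return pd.DataFrame(cells, index=order, columns=order)


def write_report(
    outdir: str | Path,
    summary: PosteriorSummary,
    ranking: RankingSummary,
    heterogeneity_summary,
    classification: pd.Series,
    baseline: pd.DataFrame | None = None,
    provenance: dict | None = None,
) -> dict[str, Path]:
    """Write the full analysis report; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    order = ranking.order
    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame, **kw) -> None:
        p = outdir / name
        df.to_csv(p, **kw)
        paths[name] = p

    save("table2.csv", table2_frame(summary, order), index_label="device_id")
    dev = summary.device_table.set_index("device_id").loc[order]
    dev["sucra"] = ranking.sucra.loc[order]
    dev["usability_class"] = classification.loc[order]
    save("device_estimates.csv", dev.round(4), index_label="device_id")
    save("sucra.csv", ranking.sucra.loc[order].round(4).to_frame())
    save("rank_probabilities.csv", ranking.rank_probs.loc[order].round(4))
    save("cumulative_ranking.csv", ranking.cumulative.loc[order].round(4))
    if baseline is not None:
        save("table1.csv", baseline, index=False)
    het_path = outdir / "heterogeneity.json"
    het_path.write_text(
        json.dumps(heterogeneity_summary.as_dict(), indent=2, sort_keys=True) + "\n"
    )
    paths["heterogeneity.json"] = het_path
    if provenance is not None:
        prov_path = outdir / "provenance.json"
        prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
        paths["provenance.json"] = prov_path
    return paths
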