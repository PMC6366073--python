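"""Light/dark proteome-transcriptome filters and concordance.

Features (protein groups or transcript classes) are measured in three
replicates each of a light-grown and a dark-adapted culture. A feature is
kept only when detected in all three replicates of at least one condition;
kept features detected in exactly one condition form the single-state
cohort with an infinite light/dark ratio. Finite per-feature log10(L/D)
ratios are computed from per-condition means of replicate intensities, and
protein vs RNA ratio concordance is summarised by a Spearman rank
correlation, overall and restricted to plastid-encoded features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

N_REPLICATES = 3
CONDITIONS = ("light", "dark")

DET_COLS = {
    "light": [f"det_light_{i}" for i in range(1, N_REPLICATES + 1)],
    "dark": [f"det_dark_{i}" for i in range(1, N_REPLICATES + 1)],
}
VAL_COLS = {
    "light": [f"val_light_{i}" for i in range(1, N_REPLICATES + 1)],
    "dark": [f"val_dark_{i}" for i in range(1, N_REPLICATES + 1)],
}
ALL_COLS = DET_COLS["light"] + DET_COLS["dark"] + VAL_COLS["light"] + VAL_COLS["dark"]


def validate_replicate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the wide 3+3 replicate layout (detection flags + values)."""
    missing = [c for c in ALL_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"replicate table missing columns {missing}; "
                         "exactly 3 replicates per condition are required")
    for cond in CONDITIONS:
        vals = table[VAL_COLS[cond]].to_numpy(float)
        if np.nanmin(vals, initial=0) < 0:
            raise ValueError("negative intensity/count values")
        det = table[DET_COLS[cond]].to_numpy(bool)
        if np.any(det & ~np.isfinite(vals)):
            raise ValueError("detected replicate without a value")
    return table


def read_long_tsv(path: str | Path) -> pd.DataFrame:
    """Read the tidy layout ``id, cond, rep, detected, value`` into the wide
    3+3 table indexed by feature id."""
    long = pd.read_csv(path, sep="\t", dtype={"id": str})
    wide = {}
    for (fid,), sub in long.groupby(["id"]):
        row = {}
        for _, r in sub.iterrows():
            row[f"det_{r['cond']}_{int(r['rep'])}"] = bool(r["detected"])
            row[f"val_{r['cond']}_{int(r['rep'])}"] = float(r["value"])
        wide[fid] = row
    df = pd.DataFrame.from_dict(wide, orient="index")
    df.index.name = "id"
    return validate_replicate_table(df)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def detections(table: pd.DataFrame, cond: str) -> pd.Series:
    return table[DET_COLS[cond]].astype(bool).sum(axis=1)


def filter_by_replicates(table: pd.DataFrame) -> pd.Index:
    """Features detected in all three replicates of at least one condition.

    The same rejection criterion applies to protein groups and to
    transcript classes.
    """
    validate_replicate_table(table)
    full = (detections(table, "light") == N_REPLICATES) | \
           (detections(table, "dark") == N_REPLICATES)
    return table.index[full]


def extract_single_state(retained: pd.Index,
                         table: pd.DataFrame) -> dict[str, pd.Index]:
    """Partition retained features into light_only / dark_only / both.

    "Only one state" means zero detections in the other condition; a
    feature fully detected in light and partially in dark belongs to
    ``both``.
    """
    sub = table.loc[retained]
    n_light = detections(sub, "light")
    n_dark = detections(sub, "dark")
    light_only = sub.index[(n_light == N_REPLICATES) & (n_dark == 0)]
    dark_only = sub.index[(n_dark == N_REPLICATES) & (n_light == 0)]
    both = sub.index.difference(light_only.union(dark_only))
    return {"light_only": light_only, "dark_only": dark_only, "both": both}


# ---------------------------------------------------------------------------
# ratios and concordance
# ---------------------------------------------------------------------------

def compute_log_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature log10 light/dark ratio from per-condition mean intensity.

    Undetected replicates contribute 0 to the condition mean. Features
    with one zero mean get an infinite-flagged ratio (the single-state
    cohort); features with both means zero are dropped with a warning.
    """
    validate_replicate_table(table)
    mean_l = table[VAL_COLS["light"]].fillna(0.0).mean(axis=1)
    mean_d = table[VAL_COLS["dark"]].fillna(0.0).mean(axis=1)
    both_zero = (mean_l == 0) & (mean_d == 0)
    if both_zero.any():
        logger.warning("%d features with zero intensity in both conditions "
                       "dropped", int(both_zero.sum()))
    out = pd.DataFrame(index=table.index[~both_zero])
    ml, md = mean_l[~both_zero], mean_d[~both_zero]
    with np.errstate(divide="ignore"):
        ratio = np.log10(ml.to_numpy()) - np.log10(md.to_numpy())
    out["log10_ratio"] = ratio
    out["single_state"] = np.select(
        [md.to_numpy() == 0, ml.to_numpy() == 0],
        ["light_only", "dark_only"], default="none",
    )
    return out


@dataclass
class ConcordanceResult:
    pairs: pd.DataFrame            # gene_id, protein_ratio, rna_ratio, plastid_encoded
    rho_overall: float
    rho_plastid: float
    n_pairs: int
    n_plastid: int

    def summary(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_plastid": self.n_plastid,
            "spearman_rho_overall": self.rho_overall,
            "spearman_rho_plastid": self.rho_plastid,
        }


def pair_and_correlate(protein_ratios: pd.DataFrame,
                       rna_ratios: pd.DataFrame,
                       id_map: Mapping[str, str],
                       plastid_encoded: set[str] | None = None
                       ) -> ConcordanceResult:
    """Pair finite protein and RNA log ratios through a many-to-one
    transcript-to-protein-group map and rank-correlate them.

    When several transcripts map to one protein group their finite ratios
    are averaged before pairing. ``plastid_encoded`` names protein groups
    whose genes reside on the plastid genome; their concordance is
    reported separately.
    """
    plastid_encoded = plastid_encoded or set()
    prot = protein_ratios.loc[protein_ratios["single_state"] == "none",
                              "log10_ratio"]
    rna = rna_ratios.loc[rna_ratios["single_state"] == "none", "log10_ratio"]

    mapped = pd.Series({t: g for t, g in id_map.items() if t in rna.index})
    if mapped.empty or prot.empty:
        logger.warning("no overlapping features between protein and RNA tables")
        empty = pd.DataFrame(columns=["gene_id", "protein_ratio", "rna_ratio",
                                      "plastid_encoded"])
        return ConcordanceResult(empty, float("nan"), float("nan"), 0, 0)

    rna_by_group = rna.loc[mapped.index].groupby(mapped).mean()
    common = prot.index.intersection(rna_by_group.index)
    pairs = pd.DataFrame({
        "gene_id": common,
        "protein_ratio": prot.loc[common].to_numpy(),
        "rna_ratio": rna_by_group.loc[common].to_numpy(),
        "plastid_encoded": np.array([g in plastid_encoded for g in common],
                                    dtype=bool),
    }).reset_index(drop=True)

    rho_overall = _spearman(pairs["protein_ratio"], pairs["rna_ratio"])
    sub = pairs[pairs["plastid_encoded"]]
    rho_plastid = _spearman(sub["protein_ratio"], sub["rna_ratio"])
    return ConcordanceResult(pairs, rho_overall, rho_plastid,
                             len(pairs), len(sub))


def _spearman(x: pd.Series, y: pd.Series) -> float:
    if len(x) < 2:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def filter_report(table: pd.DataFrame) -> dict:
    """Count funnel of the replicate filter and single-state extraction."""
    retained = filter_by_replicates(table)
    parts = extract_single_state(retained, table)
    return {
        "n_input": int(len(table)),
        "n_retained": int(len(retained)),
        "n_single_state": int(len(parts["light_only"]) + len(parts["dark_only"])),
        "n_light_only": int(len(parts["light_only"])),
        "n_dark_only": int(len(parts["dark_only"])),
        "n_both": int(len(parts["both"])),
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def plot_concordance(result: ConcordanceResult, path: str | Path) -> None:
    """Scatter of protein vs RNA log10 ratios (plastid-encoded highlighted)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    p = result.pairs
    ax.scatter(p.loc[~p["plastid_encoded"], "rna_ratio"],
               p.loc[~p["plastid_encoded"], "protein_ratio"],
               s=6, alpha=0.4, label="nuclear")
    ax.scatter(p.loc[p["plastid_encoded"], "rna_ratio"],
               p.loc[p["plastid_encoded"], "protein_ratio"],
               s=10, color="tab:green", label="plastid-encoded")
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.set_xlabel("RNA log10(L/D)")
    ax.set_ylabel("protein log10(L/D)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
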