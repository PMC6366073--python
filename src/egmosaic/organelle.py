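"""Organellar proteome inclusion rules.

Mitochondrial and plastid proteome membership is decided from precomputed
per-protein tool evidence (targeting-signal scores, reference-proteome
orthologs, annotation flags, manual curation), never by re-running the
predictors. Each included protein carries a single provenance category so
category counts partition the final set.

Mitochondrial rule (priority order, first match wins):
  i.   targeting-prediction mitochondrial score strictly above a threshold
       (default 0.9),
  ii.  ortholog in a reference mitoproteome not associated with
       non-mitochondrial functions,
  iii. annotated mitochondrial by sequence-similarity annotation, except
       members of the MTERF family,
  iv.  manual addition.

Plastid rule (two stages): a protein enters the preliminary set when a
secretory signal predictor (either of two tools) is positive AND the
chloroplast transit-peptide predictor — run on the mature sequence, i.e.
cut at the predicted cleavage site and truncated to 200 residues — is also
positive. The final set is the union of the preliminary set with
reference-chloroplast-proteome orthologs and manual additions, which are
admitted regardless of targeting signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MITO_SCORE_MIN = 0.9
DEFAULT_CHLOROP_MAX_LEN = 200

#: Expected ToolScoreTable columns with their fill value when absent.
TOOLSCORE_COLUMNS: dict[str, object] = {
    "targetp_mito_score": 0.0,
    "ref_mito_ortholog": False,
    "ortholog_non_mito_function": False,
    "blast2go_mito": False,
    "mterf_family": False,
    "manual_mito": False,
    "signalp_positive": False,
    "signalp_cleavage": pd.NA,
    "predisi_positive": False,
    "predisi_cleavage": pd.NA,
    "chlorop_positive": False,
    "at_chloro_ortholog": False,
    "manual_plastid": False,
    "sequence_length": 0,
}

MITO_CATEGORIES = ("targetp", "ortholog", "blast2go", "manual")
PLASTID_PRELIM_CATEGORIES = ("signalp_chlorop", "predisi_chlorop", "both_chlorop")


@dataclass(frozen=True)
class OrganelleCall:
    protein_id: str
    compartment: str  # mitochondrion | plastid
    category: str


def load_toolscore_table(path: str | Path) -> pd.DataFrame:
    """Read a tool-score TSV indexed by ``protein_id``; absent columns are
    filled with their neutral default and warned about."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    df = df.set_index("protein_id")
    return validate_toolscore_table(df)


def validate_toolscore_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col, default in TOOLSCORE_COLUMNS.items():
        if col not in df.columns:
            logger.warning("tool-score table missing column %r; filling with %r",
                           col, default)
            df[col] = default
        elif default is not pd.NA and df[col].isna().any():
            filled = df[col].astype(object)
            filled[filled.isna()] = default  # sparse TSV cells
            df[col] = filled.infer_objects(copy=False)
    bad = (df["targetp_mito_score"] < 0) | (df["targetp_mito_score"] > 1)
    if bad.any():
        raise ValueError("targetp_mito_score outside [0, 1] for "
                         f"{bad.sum()} proteins")
    return df


def call_mitochondrial(table: pd.DataFrame,
                       score_min: float = DEFAULT_MITO_SCORE_MIN
                       ) -> tuple[list[OrganelleCall], dict[str, int]]:
    """Apply the four-rule mitochondrial inclusion with priority attribution.

    Returns the calls plus a category breakdown; the breakdown sums to the
    number of calls because the first satisfied rule wins.
    """
    if not 0 < score_min <= 1:
        raise ValueError("score_min must be in (0, 1]")
    table = validate_toolscore_table(table)
    calls: list[OrganelleCall] = []
    breakdown = dict.fromkeys(MITO_CATEGORIES, 0)
    for pid, row in table.iterrows():
        if row["targetp_mito_score"] > score_min:
            cat = "targetp"
        elif row["ref_mito_ortholog"] and not row["ortholog_non_mito_function"]:
            cat = "ortholog"
        elif row["blast2go_mito"] and not row["mterf_family"]:
            cat = "blast2go"
        elif row["manual_mito"]:
            cat = "manual"
        else:
            continue
        calls.append(OrganelleCall(str(pid), "mitochondrion", cat))
        breakdown[cat] += 1
    return calls, breakdown


def prepare_chlorop_input(sequence: str, cleavage: int,
                          max_len: int = DEFAULT_CHLOROP_MAX_LEN) -> str:
    """Mature-protein window for transit-peptide prediction.

    Cuts the sequence after the 1-based ``cleavage`` residue and truncates
    the remainder to at most ``max_len`` residues.
    """
    if not 1 <= cleavage < len(sequence):
        raise ValueError(
            f"cleavage site {cleavage} outside sequence of length {len(sequence)}"
        )
    return sequence[cleavage:cleavage + max_len]


def call_plastid_preliminary(table: pd.DataFrame) -> list[OrganelleCall]:
    """Signal-then-transit-peptide gate for the preliminary plastid set.

    Included iff (SignalP-positive OR PrediSI-positive) AND
    ChloroP-positive; the category records which signal tool(s) fired.
    A ChloroP flag without any signal-tool positive is logged as an
    inconsistency (the transit-peptide step only ran downstream of a
    signal call) and the protein is not included.
    """
    table = validate_toolscore_table(table)
    calls: list[OrganelleCall] = []
    sp = table["signalp_positive"].astype(bool)
    pd_ = table["predisi_positive"].astype(bool)
    cp = table["chlorop_positive"].astype(bool)
    orphan = cp & ~(sp | pd_)
    if orphan.any():
        logger.warning("%d proteins ChloroP-positive without any signal-tool "
                       "positive; ignored", int(orphan.sum()))
    for pid in table.index[(sp | pd_) & cp]:
        s, p = bool(sp[pid]), bool(pd_[pid])
        cat = "both_chlorop" if (s and p) else (
            "signalp_chlorop" if s else "predisi_chlorop")
        calls.append(OrganelleCall(str(pid), "plastid", cat))
    return calls


def finalize_plastid(preliminary: list[OrganelleCall],
                     table: pd.DataFrame) -> list[OrganelleCall]:
    """Union the preliminary set with reference-chloroplast orthologs and
    manual additions; already-included proteins keep their category."""
    table = validate_toolscore_table(table)
    included = {c.protein_id for c in preliminary}
    calls = list(preliminary)
    for pid in table.index[table["at_chloro_ortholog"].astype(bool)]:
        if str(pid) not in included:
            calls.append(OrganelleCall(str(pid), "plastid", "atchloro_ortholog"))
            included.add(str(pid))
    for pid in table.index[table["manual_plastid"].astype(bool)]:
        if str(pid) not in included:
            calls.append(OrganelleCall(str(pid), "plastid", "manual"))
            included.add(str(pid))
    return calls


def category_breakdown(calls: list[OrganelleCall]) -> dict[str, int]:
    out: dict[str, int] = {}
    for c in calls:
        out[c.category] = out.get(c.category, 0) + 1
    return out


def calls_to_frame(calls: list[OrganelleCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "protein_id": [c.protein_id for c in calls],
        "compartment": [c.compartment for c in calls],
        "category": [c.category for c in calls],
    })


def report_dual_compartment(mito: list[OrganelleCall],
                            plastid: list[OrganelleCall]) -> set[str]:
    """Proteins satisfying both compartments' rules, reported with a warning
    (both outputs keep them)."""
    dual = {c.protein_id for c in mito} & {c.protein_id for c in plastid}
    if dual:
        logger.warning("%d proteins called in both mitochondrial and plastid "
                       "sets", len(dual))
    return dual
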