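"""Comparative secretome analysis: from peptide tables to effector candidates.

The experimental design compares culture-supernatant proteomes of four
strains — wild type (WT), a TtsI over-expressor (OETtsI), a T3SS deletion
mutant (dT3SS) and the deletion mutant over-expressing TtsI
(dT3SS_OETtsI). A protein secreted through the T3SS is expected in the
supernatant of the secretion-competent strains and never in the mutants
lacking the apparatus; cytosolic/membrane proteins arriving via outer
membrane vesicles (OMVs) or lysis appear regardless of the T3SS and are
filtered by localization class, and remaining unknowns by symbiotic-island
membership of their gene.

Stages: target-decoy peptide FDR control -> two-unique-peptide protein
validation per run -> strain-level detection matrix -> comparative
candidate rule -> localization / island filters -> OMV and needle-component
annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

T3SS_POSITIVE = ("WT", "OETtsI")
T3SS_NEGATIVE = ("dT3SS", "dT3SS_OETtsI")
STRAINS = T3SS_POSITIVE + T3SS_NEGATIVE

EXCLUDED_LOCALIZATIONS = ("membrane", "cytosolic", "secreted_classical")

PEPTIDE_COLUMNS = ["run_id", "peptide", "proteins", "score", "is_decoy"]


class FDRWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# target-decoy FDR
# ---------------------------------------------------------------------------

@dataclass
class FdrResult:
    retained: pd.DataFrame
    cutoff: float
    achieved_fdr: float
    feasible: bool


def peptide_fdr_filter(peptides: pd.DataFrame, fdr_max: float = 0.01) -> FdrResult:
    """Pick the most permissive score cutoff controlling the decoy FDR.

    The cutoff is the smallest observed score s such that
    #{decoys with score >= s} / #{targets with score >= s} <= ``fdr_max``;
    targets at or above the cutoff are retained, decoys are dropped from all
    downstream stages. If no threshold achieves the bound, an empty set is
    returned with a warning.
    """
    missing = [c for c in PEPTIDE_COLUMNS if c not in peptides.columns]
    if missing:
        raise ValueError(f"peptide table missing columns {missing}")
    scores = peptides["score"].values.astype(float)
    if not np.isfinite(scores).all():
        raise ValueError("peptide scores must be finite")
    is_decoy = peptides["is_decoy"].astype(bool).values
    if is_decoy.all() or (~is_decoy).all():
        raise ValueError("need both target and decoy peptides for FDR control")

    # count targets/decoys at or above each candidate threshold
    order = np.argsort(scores)[::-1]
    sorted_scores = scores[order]
    decoy_sorted = is_decoy[order]
    cum_decoys = np.cumsum(decoy_sorted)
    cum_targets = np.cumsum(~decoy_sorted)
    # last index of each tied score block = counts ">= score"
    uniq_scores, last_idx = np.unique(-sorted_scores, return_index=True)
    # np.unique on negated scores gives ascending -> descending originals;
    # first occurrence index of the *next* block minus one is the block end
    block_ends = np.r_[last_idx[1:] - 1, len(sorted_scores) - 1]
    thresholds = -uniq_scores                      # descending
    fdr_at = cum_decoys[block_ends] / np.maximum(cum_targets[block_ends], 1)
    ok = (fdr_at <= fdr_max) & (cum_targets[block_ends] > 0)
    if not ok.any():
        warnings.warn("no score cutoff achieves the requested FDR; "
                      "returning an empty peptide set", FDRWarning)
        return FdrResult(retained=peptides.iloc[0:0].copy(),
                         cutoff=np.inf, achieved_fdr=np.nan, feasible=False)
    # smallest qualifying score = last qualifying entry in descending order
    i = int(np.flatnonzero(ok)[-1])
    cutoff = float(thresholds[i])
    achieved = float(fdr_at[i])
    keep = (~is_decoy) & (scores >= cutoff)
    return FdrResult(retained=peptides.loc[keep].copy(), cutoff=cutoff,
                     achieved_fdr=achieved, feasible=True)


# ---------------------------------------------------------------------------
# protein-level validation
# ---------------------------------------------------------------------------

def call_proteins(retained: pd.DataFrame, min_unique: int = 2) -> pd.DataFrame:
    """Per-run protein detections from FDR-filtered peptides.

    A protein is detected in a run iff >= ``min_unique`` distinct peptide
    sequences map to it *uniquely* (a peptide shared between proteins never
    counts toward anyone's uniqueness). Returns one row per (run_id,
    protein_id) with n_unique_peptides and best score.
    """
    if retained.empty:
        return pd.DataFrame(columns=["run_id", "protein_id",
                                     "n_unique_peptides", "best_score"])
    pep = retained.copy()
    pep["protein_list"] = pep["proteins"].astype(str).str.split(";")
    unique_mask = pep["protein_list"].str.len() == 1
    uni = pep.loc[unique_mask].copy()
    uni["protein_id"] = uni["protein_list"].str[0]
    grouped = (uni.groupby(["run_id", "protein_id"])
               .agg(n_unique_peptides=("peptide", "nunique"),
                    best_score=("score", "max"))
               .reset_index())
    detected = grouped[grouped["n_unique_peptides"] >= min_unique]
    return detected.reset_index(drop=True)


# ---------------------------------------------------------------------------
# detection matrix
# ---------------------------------------------------------------------------

@dataclass
class DetectionMatrix:
    presence: pd.DataFrame        # protein x strain booleans
    support: pd.DataFrame         # protein x strain run counts
    runs_per_strain: dict[str, int]


def build_detection_matrix(detections: pd.DataFrame, run_design: pd.DataFrame,
                           rule: str = "any") -> DetectionMatrix:
    """Collapse per-run detections into strain-level presence.

    ``rule='any'`` calls a protein present in a strain when detected in at
    least one run; ``rule='majority'`` requires more than half of that
    strain's runs.
    """
    if rule not in {"any", "majority"}:
        raise ValueError(f"unknown detection rule {rule!r}")
    if not {"run_id", "strain"}.issubset(run_design.columns):
        raise ValueError("run design needs columns run_id, strain")
    runs_per_strain = run_design.groupby("strain")["run_id"].nunique().to_dict()
    strains = list(run_design["strain"].unique())
    merged = detections.merge(run_design[["run_id", "strain"]], on="run_id",
                              how="left")
    if merged["strain"].isna().any():
        bad = merged.loc[merged["strain"].isna(), "run_id"].unique()
        raise ValueError(f"runs absent from design: {list(bad)}")
    support = (merged.groupby(["protein_id", "strain"])["run_id"].nunique()
               .unstack(fill_value=0)
               .reindex(columns=strains, fill_value=0))
    if rule == "any":
        presence = support >= 1
    else:
        need = pd.Series(runs_per_strain).reindex(strains) / 2.0
        presence = support.gt(need, axis=1)
    presence = presence.sort_index()
    support = support.sort_index()
    return DetectionMatrix(presence=presence, support=support,
                           runs_per_strain=runs_per_strain)


def presence_from_table(table: pd.DataFrame) -> DetectionMatrix:
    """Build a DetectionMatrix from a protein x strain boolean table
    (e.g. a fixture of published presence/absence calls)."""
    presence = table.astype(bool)
    support = presence.astype(int)
    return DetectionMatrix(presence=presence, support=support,
                           runs_per_strain={s: 1 for s in presence.columns})


# ---------------------------------------------------------------------------
# comparative candidate rule
# ---------------------------------------------------------------------------

def candidate_rule(matrix: DetectionMatrix) -> pd.DataFrame:
    """The comparative T3SS-dependence call.

    candidate_secreted <=> present in WT or OETtsI supernatant AND absent
    from both T3SS-mutant supernatants. ``strict_intersection`` marks the
    subset present in both WT and OETtsI.
    """
    pres = matrix.presence
    missing = [s for s in STRAINS if s not in pres.columns]
    if missing:
        raise ValueError(f"detection matrix lacks strains {missing}")
    pos = pres[list(T3SS_POSITIVE)].any(axis=1)
    neg = pres[list(T3SS_NEGATIVE)].any(axis=1)
    return pd.DataFrame({
        "candidate_secreted": pos & ~neg,
        "strict_intersection": pres[list(T3SS_POSITIVE)].all(axis=1) & ~neg,
        "present_in_t3ss_mutant": neg,
    }, index=pres.index)


# ---------------------------------------------------------------------------
# filters and annotation flags
# ---------------------------------------------------------------------------

@dataclass
class SecretomeCall:
    protein_id: str
    candidate: bool
    status: str
    exclusion_reasons: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def localization_filter(candidates: pd.DataFrame,
                        annotations: pd.DataFrame,
                        require_island: bool = True) -> pd.DataFrame:
    """Apply localization-class and island exclusions to candidate calls.

    ``annotations`` maps protein_id -> localization_class (and in_island
    when the island filter is on); unannotated proteins default to class
    ``unknown``. Membrane, cytosolic and classically secreted proteins are
    excluded; proteins of class ``unknown`` or ``predicted_effector`` are
    kept. With ``require_island`` (the default for effector calling),
    candidates whose gene lies outside the symbiotic island are excluded.
    """
    ann = annotations.set_index("protein_id") if "protein_id" in annotations.columns \
        else annotations
    loc = ann["localization_class"].reindex(candidates.index).fillna("unknown")
    island = (ann["in_island"].reindex(candidates.index).fillna(False).astype(bool)
              if "in_island" in ann.columns
              else pd.Series(True, index=candidates.index))

    out = candidates.copy()
    out["localization_class"] = loc
    out["in_island"] = island
    reasons = []
    for pid in out.index:
        r = []
        if out.at[pid, "present_in_t3ss_mutant"]:
            r.append("present_in_t3ss_mutant")
        if loc[pid] in EXCLUDED_LOCALIZATIONS:
            r.append(loc[pid])
        elif require_island and not island[pid]:
            # the island criterion is applied to proteins that survive the
            # localization filter (unknown / predicted_effector classes)
            r.append("outside_island")
        reasons.append(r)
    out["exclusion_reasons"] = [";".join(r) for r in reasons]
    out["candidate"] = out["candidate_secreted"] & (out["exclusion_reasons"] == "")
    return out


def omv_flag(calls: pd.DataFrame, omv_reference: pd.Series | None) -> pd.DataFrame:
    """Annotate (never exclude) proteins matching an OMV-background list."""
    out = calls.copy()
    if omv_reference is None or len(omv_reference) == 0:
        if omv_reference is None:
            warnings.warn("no OMV reference list supplied; all flags false",
                          UserWarning)
        out["omv_background_match"] = False
        return out
    ref = set(omv_reference.astype(str))
    out["omv_background_match"] = out.index.astype(str).isin(ref)
    return out


def needle_annotation(calls: pd.DataFrame,
                      machinery_ids: set[str] | list[str]) -> pd.DataFrame:
    """Separate T3SS machinery (needle/translocon) proteins from effectors.

    Machinery proteins with the candidate secretion pattern are flagged
    ``needle_component`` and removed from the effector-candidate set;
    machinery present in T3SS-mutant supernatants is reported as secreted
    T3SS-independently (the translocon can reach the supernatant without a
    functional needle); machinery never detected is reported not secreted
    by :func:`machinery_report`.
    """
    out = calls.copy()
    mach = out.index.isin(set(machinery_ids))
    out["needle_component"] = mach & out["candidate_secreted"]
    out.loc[out["needle_component"], "candidate"] = False

    status = np.full(len(out), "", dtype=object)
    status[out["candidate"].values] = "effector_candidate"
    status[(~out["candidate"] & ~np.asarray(mach)
            & (out["exclusion_reasons"] != "")).values] = "excluded"
    status[(mach & out["candidate_secreted"]).values] = "needle_component"
    status[(mach & out["present_in_t3ss_mutant"]).values] = "secreted_t3ss_independent"
    status[(~mach & ~out["candidate"] & (out["exclusion_reasons"] == "")).values] = \
        "not_t3ss_dependent"
    out["status"] = status
    return out


def machinery_report(calls: pd.DataFrame,
                     machinery_ids: set[str] | list[str]) -> pd.DataFrame:
    """Per-machinery-protein secretion status, including never-detected ones."""
    rows = []
    for pid in sorted(set(machinery_ids)):
        if pid in calls.index:
            rows.append({"protein_id": pid, "status": calls.at[pid, "status"]})
        else:
            rows.append({"protein_id": pid, "status": "not_secreted"})
    return pd.DataFrame(rows).set_index("protein_id")


def venn_summary(matrix: DetectionMatrix) -> pd.DataFrame:
    """Set sizes per strain and pairwise unions/intersections."""
    pres = matrix.presence
    rows = []
    for s in pres.columns:
        rows.append({"set": s, "size": int(pres[s].sum())})
    cols = list(pres.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rows.append({"set": f"{a}&{b}", "size": int((pres[a] & pres[b]).sum())})
            rows.append({"set": f"{a}|{b}", "size": int((pres[a] | pres[b]).sum())})
    return pd.DataFrame(rows)
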