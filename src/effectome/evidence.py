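"""Per-locus evidence integration and effector confidence tiers.

Each locus accumulates boolean evidence along three assayable axes:

* in-silico motif / transcriptional regulation — an upstream tts-box
  and/or TtsI-dependent expression;
* secretion — T3SS-dependent presence in the culture supernatant;
* prior knowledge — an earlier in-silico prediction and/or homology to a
  known effector.

Tiers: CONFIRMED_ALL_METHODS (motif + regulation + secretion),
PREDICTION_REJECTED (a prior prediction contradicted by both experimental
assays), CANDIDATE_MULTI (two or more axes, not confirmed),
CANDIDATE_SINGLE (one axis), NOT_EFFECTOR (nothing, or TtsI-dependence
alone for a gene outside the symbiotic island — housekeeping regulon
members are retained in the report but not treated as effector evidence).
A near-miss regulation call (effect size or significance just below
cutoff) is weak experimental support: it blocks rejection without
counting as a positive regulation call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

TIERS = ["CONFIRMED_ALL_METHODS", "CANDIDATE_MULTI", "CANDIDATE_SINGLE",
         "PREDICTION_REJECTED", "NOT_EFFECTOR"]

TIER_RANK = {"CONFIRMED_ALL_METHODS": 4, "CANDIDATE_MULTI": 3,
             "CANDIDATE_SINGLE": 2, "PREDICTION_REJECTED": 1,
             "NOT_EFFECTOR": 1}

EVIDENCE_FLAGS = ["has_tts_box", "ttsI_regulated", "genistein_induced",
                  "t3ss_secreted", "homology_known_effector",
                  "prior_in_silico_prediction", "in_island",
                  "near_miss_regulation"]


@dataclass
class EvidenceRecord:
    locus_id: str
    has_tts_box: bool = False
    ttsI_regulated: bool = False
    genistein_induced: bool = False
    t3ss_secreted: bool = False
    homology_known_effector: bool = False
    prior_in_silico_prediction: bool = False
    in_island: bool = False
    near_miss_regulation: bool = False
    provenance: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# merging evidence streams
# ---------------------------------------------------------------------------

def build_evidence(motif_loci: Mapping[str, bool] | pd.Series | None = None,
                   regulation: pd.DataFrame | None = None,
                   secretome_calls: pd.DataFrame | None = None,
                   priors: pd.DataFrame | None = None,
                   homology: pd.DataFrame | None = None,
                   island_membership: Mapping[str, bool] | pd.Series | None = None,
                   id_map: Mapping[str, str] | None = None,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Merge evidence streams into one record per locus.

    ``id_map`` translates protein ids to gene/locus ids (identity when
    omitted). Any flag a stream does not observe stays False with
    provenance "unobserved"; proteins that cannot be mapped to a locus are
    returned in the unmapped report rather than raising.

    Returns (records DataFrame indexed by locus_id, unmapped protein ids).
    """
    id_map = dict(id_map or {})
    records: dict[str, EvidenceRecord] = {}
    unmapped: list[str] = []

    def rec(locus: str) -> EvidenceRecord:
        if locus not in records:
            records[locus] = EvidenceRecord(locus_id=locus)
        return records[locus]

    if motif_loci is not None:
        for locus, has in pd.Series(motif_loci).items():
            r = rec(str(locus))
            r.has_tts_box = bool(has)
            r.provenance["has_tts_box"] = "motif_scan"

    if regulation is not None:
        for locus, row in regulation.iterrows():
            r = rec(str(locus))
            r.ttsI_regulated = bool(row.get("ttsI_dependent", False))
            r.genistein_induced = bool(row.get("genistein_induced", False))
            r.near_miss_regulation = bool(row.get("near_miss", False))
            r.provenance["ttsI_regulated"] = "transcriptome"

    if secretome_calls is not None:
        for pid, row in secretome_calls.iterrows():
            locus = id_map.get(str(pid), str(pid))
            if locus is None:
                unmapped.append(str(pid))
                continue
            r = rec(locus)
            r.t3ss_secreted = bool(row.get("candidate", row.get("candidate_secreted", False)))
            r.provenance["t3ss_secreted"] = "secretome"

    if priors is not None:
        ids = priors["locus_id"] if "locus_id" in priors.columns else priors.index
        for locus in ids:
            r = rec(str(locus))
            r.prior_in_silico_prediction = True
            r.provenance["prior_in_silico_prediction"] = "prior_table"

    if homology is not None:
        ids = homology["locus_id"] if "locus_id" in homology.columns else homology.index
        for locus in ids:
            r = rec(str(locus))
            r.homology_known_effector = True
            r.provenance["homology_known_effector"] = "homology_table"

    if island_membership is not None:
        for locus, val in pd.Series(island_membership).items():
            if str(locus) in records:
                records[str(locus)].in_island = bool(val)
                records[str(locus)].provenance["in_island"] = "island_bed"

    rows = []
    for locus in sorted(records):
        r = records[locus]
        row = {f: getattr(r, f) for f in EVIDENCE_FLAGS}
        row["locus_id"] = locus
        row["provenance"] = ";".join(f"{k}={v}" for k, v in sorted(r.provenance.items()))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["locus_id", *EVIDENCE_FLAGS, "provenance"])
    if not frame.empty:
        frame = frame.set_index("locus_id")
    else:
        frame.index.name = "locus_id"
    return frame, sorted(set(unmapped))


# ---------------------------------------------------------------------------
# tier classification
# ---------------------------------------------------------------------------

def classify_tier(record: Mapping | pd.Series) -> str:
    """Assign one of the five effector tiers to an evidence record."""
    tts = bool(record["has_tts_box"])
    reg = bool(record["ttsI_regulated"])
    sec = bool(record["t3ss_secreted"])
    prior = bool(record["prior_in_silico_prediction"])
    hom = bool(record["homology_known_effector"])
    near = bool(record.get("near_miss_regulation", False))
    island = bool(record.get("in_island", True))

    if tts and reg and sec:
        return "CONFIRMED_ALL_METHODS"
    if prior and not reg and not sec and not near:
        # an in-silico prediction both experimental assays failed to support
        return "PREDICTION_REJECTED"
    axes = sum([tts or reg, sec, hom or prior])
    if reg and not tts and not sec and not hom and not prior and not island:
        # TtsI-dependence alone outside the symbiotic island: regulon
        # member, reported but not an effector candidate
        return "NOT_EFFECTOR"
    if axes >= 2:
        return "CANDIDATE_MULTI"
    if axes == 1:
        return "CANDIDATE_SINGLE"
    return "NOT_EFFECTOR"


def classify_tiers(records: pd.DataFrame) -> pd.Series:
    return pd.Series({locus: classify_tier(row)
                      for locus, row in records.iterrows()},
                     name="tier").reindex(records.index)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _source(row: pd.Series) -> str:
    if row["prior_in_silico_prediction"]:
        return "prior"
    if row["t3ss_secreted"]:
        return "proteome_new"
    if row["ttsI_regulated"]:
        return "transcriptome_new"
    return "other"


def summarize(records: pd.DataFrame, tiers: pd.Series) -> dict:
    """Counts per tier, per evidence combination and per source, plus the
    locus x evidence boolean matrix and a plain-text report."""
    tier_counts = tiers.value_counts().reindex(TIERS, fill_value=0)
    source = records.apply(_source, axis=1) if not records.empty else pd.Series(dtype=object)
    source_counts = source.value_counts().to_dict()
    combo = (records[EVIDENCE_FLAGS].astype(int).astype(str).agg("".join, axis=1)
             if not records.empty else pd.Series(dtype=object))
    combo_counts = combo.value_counts().to_dict()

    matrix = records[EVIDENCE_FLAGS].copy() if not records.empty \
        else pd.DataFrame(columns=EVIDENCE_FLAGS)
    matrix["tier"] = tiers
    matrix["source"] = source

    lines = ["Effector evidence report", "=" * 24,
             f"loci considered: {len(records)}", ""]
    for tier in TIERS:
        lines.append(f"{tier:>24}: {int(tier_counts[tier])}")
    lines.append("")
    for src in ("prior", "transcriptome_new", "proteome_new", "other"):
        lines.append(f"{src:>24}: {source_counts.get(src, 0)}")
    confirmed = sorted(tiers[tiers == "CONFIRMED_ALL_METHODS"].index) \
        if len(tiers) else []
    if confirmed:
        lines += ["", "confirmed by all methods:"]
        lines += [f"  {locus}" for locus in confirmed]
    report = "\n".join(lines) + "\n"

    return {
        "tier_counts": tier_counts,
        "source_counts": source_counts,
        "combination_counts": combo_counts,
        "matrix": matrix,
        "report": report,
    }
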