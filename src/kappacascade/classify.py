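"""Direct/indirect NF-kB target calling and subunit-selectivity assignment.

A responsive gene is a *direct* target when its induction is suppressed by
IKK inhibition (BAY) and it carries inducible RelA (1 h) or Rel (18 h)
binding in replicate-common ChIP peaks; inhibitor-sensitive but unbound
genes are *indirect* targets (presumed downstream of NF-kB-induced factors).
Among direct targets, early-transient RelA-bound genes whose induction needs
RelA are RelA-selective; late/intermediate Rel-bound genes needing Rel are
Rel-dependent; direct targets unaffected by either knockout are redundant.
Genes de-repressed at 1 h in Rel-deficient cells are additionally tagged
Rel-repressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .kinetics import DOWN_CLASSES

__all__ = [
    "EvidenceTable",
    "TargetCall",
    "build_evidence",
    "call_targets",
    "classification_report",
    "predicted_label",
]

EVIDENCE_COLUMNS = [
    "bound_relA_1h", "bound_rel_18h", "wt_kinetic_class", "bay_suppressed",
    "relA_dependent_early", "rel_dependent_late", "rel_repressed_early",
    "no_data",
]


@dataclass
class EvidenceTable:
    """Per-gene evidence booleans over the responsive-gene universe."""

    table: pd.DataFrame  # indexed by gene, columns EVIDENCE_COLUMNS

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicated gene ids in evidence table")
        missing = [c for c in EVIDENCE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing evidence columns: {missing}")


def build_evidence(universe, bound_relA_1h: set, bound_rel_18h: set,
                   wt_kinetic_class: pd.Series,
                   bay_suppressed: set, relA_dependent_early: set,
                   rel_dependent_late: set, rel_repressed_early: set) -> EvidenceTable:
    """Join binding gene sets, contrast tests and kinetic classes by gene id.

    Genes of the universe absent from an input get False / 'mixed' with the
    no_data flag set.
    """
    universe = pd.Index(universe)
    if universe.duplicated().any():
        raise ValueError("duplicated gene ids in universe")
    tab = pd.DataFrame(index=universe)
    tab["bound_relA_1h"] = tab.index.isin(bound_relA_1h)
    tab["bound_rel_18h"] = tab.index.isin(bound_rel_18h)
    kc = wt_kinetic_class.reindex(universe)
    tab["no_data"] = kc.isna()
    tab["wt_kinetic_class"] = kc.fillna("mixed")
    tab["bay_suppressed"] = tab.index.isin(bay_suppressed)
    tab["relA_dependent_early"] = tab.index.isin(relA_dependent_early)
    tab["rel_dependent_late"] = tab.index.isin(rel_dependent_late)
    tab["rel_repressed_early"] = tab.index.isin(rel_repressed_early)
    return EvidenceTable(tab[EVIDENCE_COLUMNS])


@dataclass
class TargetCall:
    gene: str
    target_class: str  # direct | indirect | none
    subunit_class: str  # relA_selective | rel_dependent | redundant | rel_repressed | unassigned
    rel_repressed: bool
    evidence: pd.Series

    def __post_init__(self) -> None:
        ev = self.evidence
        if self.target_class == "indirect":
            assert not (ev.bound_relA_1h or ev.bound_rel_18h)
        if self.subunit_class == "relA_selective":
            assert self.target_class == "direct" and ev.bound_relA_1h
        if self.subunit_class == "rel_dependent":
            assert self.target_class == "direct" and ev.bound_rel_18h


def call_targets(ev: EvidenceTable) -> list[TargetCall]:
    """Apply the decision table to every gene of the evidence universe."""
    calls: list[TargetCall] = []
    for gene, row in ev.table.iterrows():
        if not row.bay_suppressed:
            calls.append(TargetCall(gene, "none", "unassigned", False, row))
            continue
        bound = row.bound_relA_1h or row.bound_rel_18h
        target = "direct" if bound else "indirect"
        sub = "unassigned"
        if target == "direct":
            early = row.wt_kinetic_class == "transient_early"
            late_ish = row.wt_kinetic_class in ("late", "intermediate")
            relA_sel = early and row.bound_relA_1h and row.relA_dependent_early
            rel_dep = late_ish and row.bound_rel_18h and row.rel_dependent_late
            if relA_sel and rel_dep:
                sub = "unassigned"  # ambiguous double dependence
            elif relA_sel:
                sub = "relA_selective"
            elif rel_dep:
                sub = "rel_dependent"
            elif not (row.relA_dependent_early or row.rel_dependent_late):
                sub = "redundant"
        repressed = bool(row.rel_repressed_early)
        if repressed and sub in ("unassigned", "redundant"):
            sub = "rel_repressed"
        calls.append(TargetCall(gene, target, sub, repressed, row))
    return calls


def predicted_label(call: TargetCall) -> str:
    """Map a rubric call to a planted-class comparison label.

    Priority: none -> null; down-kinetic responsive genes -> down_regulated;
    unbound -> indirect; then relA_selective / rel_dependent / rel_repressed
    (tag) / redundant_direct.
    """
    if call.target_class == "none":
        return "null"
    if call.evidence.wt_kinetic_class in DOWN_CLASSES:
        return "down_regulated"
    if call.target_class == "indirect":
        return "indirect"
    if call.subunit_class == "relA_selective":
        return "relA_selective"
    if call.subunit_class == "rel_dependent":
        return "rel_dependent"
    if call.rel_repressed:
        return "rel_repressed"
    if call.subunit_class == "redundant":
        return "redundant_direct"
    return "direct_unassigned"


def classification_report(calls: list[TargetCall], truth: pd.Series | None = None) -> dict:
    """Class counts; with truth labels, per-class precision/recall/F1 and a
    confusion matrix.

    ``truth`` maps gene id -> planted class (null genes may be absent; they
    default to 'null').
    """
    pred = pd.Series({c.gene: predicted_label(c) for c in calls}, dtype=object)
    out: dict = {"counts": pred.value_counts().to_dict(), "n_genes": len(pred)}
    if truth is None or len(calls) == 0:
        return out
    # genes never entering the responsive universe are implicitly null calls
    pred = pred.reindex(pred.index.union(truth.index)).fillna("null")
    y_true = truth.reindex(pred.index).fillna("null").astype(str)
    labels = sorted(set(y_true) | set(pred))
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, pred, labels=labels, zero_division=0.0
    )
    out["per_class"] = {
        lab: {"precision": float(p), "recall": float(r), "f1": float(f), "support": int(s)}
        for lab, p, r, f, s in zip(labels, prec, rec, f1, support)
    }
    out["confusion"] = pd.crosstab(y_true.rename("truth"), pred.rename("predicted"))
    return out
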