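"""Gene-level subcellular localization from per-isoform predictions.

Per-isoform predictions (TargetP-style: compartment + Reliability Class,
RC 1 = most reliable) are collapsed to one of five gene-level labels:
Chloroplast, Mitochondrion, Secretory, Other or Uncertain. Among isoforms
predicted to a targeting compartment (C/M/S) the one with the lowest RC
wins; if distinct compartments tie at that lowest RC the gene is Uncertain
(agreeing isoforms at equal RC are not a tie); a gene with no C/M/S
prediction at all is Other.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genic_features import compare_sets
from .lineage_classifier import round_half_up

__all__ = [
    "IsoformLocalizationPrediction",
    "COMPARTMENTS",
    "GENE_LABELS",
    "assign_gene_localization",
    "assign_all_genes",
    "localization_contingency",
    "read_predictions",
    "write_predictions",
]

COMPARTMENTS = ("Chloroplast", "Mitochondrion", "Secretory", "Other")
TARGETING = ("Chloroplast", "Mitochondrion", "Secretory")
GENE_LABELS = COMPARTMENTS + ("Uncertain",)


@dataclass(frozen=True)
class IsoformLocalizationPrediction:
    isoform_id: str
    gene_id: str
    compartment: str
    reliability_class: int

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if not (1 <= self.reliability_class <= 5):
            raise ValueError("reliability class must be 1..5")


def assign_gene_localization(
    predictions: list[IsoformLocalizationPrediction],
) -> str:
    """Collapse one gene's isoform predictions to a single label."""
    if not predictions:
        raise ValueError("a gene needs >= 1 prediction")
    targeting = [p for p in predictions if p.compartment in TARGETING]
    if not targeting:
        return "Other"
    best_rc = min(p.reliability_class for p in targeting)
    compartments = {
        p.compartment for p in targeting if p.reliability_class == best_rc
    }
    if len(compartments) > 1:
        return "Uncertain"
    return next(iter(compartments))


def assign_all_genes(
    predictions: list[IsoformLocalizationPrediction],
) -> dict[str, str]:
    by_gene: dict[str, list[IsoformLocalizationPrediction]] = {}
    for p in predictions:
        by_gene.setdefault(p.gene_id, []).append(p)
    return {gid: assign_gene_localization(ps) for gid, ps in by_gene.items()}


def localization_contingency(
    assignments: dict[str, str],
    labels: dict[str, str],
) -> pd.DataFrame:
    """Counts/percentages per gene-set label and per-compartment chi2 tests.

    For each (set, compartment) cell, the chi-square compares the
    compartment proportion within the set against the complement of the
    set (2x2, no continuity correction). Percentages rounded half-up to
    one decimal.
    """
    gene_ids = [g for g in assignments if g in labels]
    set_labels = sorted(set(labels[g] for g in gene_ids))
    rows = []
    for set_label in set_labels:
        in_set = [g for g in gene_ids if labels[g] == set_label]
        out_set = [g for g in gene_ids if labels[g] != set_label]
        for comp in GENE_LABELS:
            a = sum(1 for g in in_set if assignments[g] == comp)
            c = sum(1 for g in out_set if assignments[g] == comp)
            pct = round_half_up(100 * a / len(in_set)) if in_set else 0.0
            chi2 = p = None
            if out_set and 0 < a + c < len(gene_ids):
                try:
                    chi2, p = compare_sets(
                        (a, len(in_set) - a),
                        (c, len(out_set) - c),
                        "chi_square_proportion",
                    )
                except ValueError:
                    pass
            rows.append(
                {
                    "set": set_label,
                    "compartment": comp,
                    "n_genes": a,
                    "pct": pct,
                    "chi2": chi2,
                    "p_value": p,
                }
            )
        rows.append(
            {
                "set": set_label,
                "compartment": "Total",
                "n_genes": len(in_set),
                "pct": 100.0,
                "chi2": None,
                "p_value": None,
            }
        )
    return pd.DataFrame(rows)


def read_predictions(path) -> list[IsoformLocalizationPrediction]:
    """TargetP-style TSV: isoform, gene, compartment, reliability class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        IsoformLocalizationPrediction(
            r["isoform_id"], r["gene_id"], r["compartment"], int(r["rc"])
        )
        for r in df.to_dict("records")
    ]


def write_predictions(preds: list[IsoformLocalizationPrediction], path) -> None:
    pd.DataFrame(
        [
            {
                "isoform_id": p.isoform_id,
                "gene_id": p.gene_id,
                "compartment": p.compartment,
                "rc": p.reliability_class,
            }
            for p in preds
        ]
    ).to_csv(path, sep="\t", index=False)
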