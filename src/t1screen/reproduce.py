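"""Re-analysis of a deposited screening dataset from processed tables.

This entry point reruns the calibration and classification arithmetic of
the screen on its published processed data.  It does not download anything:
point ``data_dir`` at a directory containing CSV exports of the deposited
tables (the processed relaxation-factor matrix and supplementary rosters):

``interactions.csv``
    long-format pair table (protein_id, metabolite_id, delta_rf) over the
    full enzyme x metabolite grid;
``reference.csv``
    known interactions (protein_id, metabolite_id, type);
``similarity.csv``
    maximum chemical similarity per pair (protein_id, metabolite_id,
    max_similarity).
"""

from __future__ import annotations

from pathlib import Path

from .benchmark import auc, confusion_at_cutoff, roc_curve, select_cutoff
from .classify import classification_summary, classify_binding_mode
from .interactions import read_interaction_table
from .tables import read_reference_set, read_similarity_table

REQUIRED_FILES = ("interactions.csv", "reference.csv", "similarity.csv")


def reproduce_published_analysis(data_dir: str | Path, target_fpr: float = 0.05) -> dict:
    """Recompute the headline numbers of a screen from its processed tables.

    Returns the ROC-calibrated cutoff at the target FPR, the detection
    count, mean similarity among detections, the allosteric count among
    novel detections, the number of proteins without any detection, and the
    maximum detections per protein (with the proteins achieving it).
    """
    data_dir = Path(data_dir)
    missing = [f for f in REQUIRED_FILES if not (data_dir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"deposited-data exports not found in {data_dir}: missing {missing}. "
            "Export the processed interaction matrix, the known-interaction "
            "table and the similarity table to these CSVs to run the full "
            "re-analysis."
        )
    matrix = read_interaction_table(data_dir / "interactions.csv")
    reference = read_reference_set(data_dir / "reference.csv")
    similarity = read_similarity_table(data_dir / "similarity.csv")

    roc = roc_curve(matrix, reference)
    cutoff, tpr, fpr = select_cutoff(roc, target_fpr)
    counts = confusion_at_cutoff(matrix, reference, cutoff)
    detections = matrix.detections(cutoff)
    classified = classify_binding_mode(detections, similarity, reference)
    summary = classification_summary(classified)

    novel = [c for c in classified if not c.known]
    novel_allosteric = sum(1 for c in novel if c.mode == "allosteric_candidate")
    per_protein, per_metabolite = matrix.marginals(cutoff)
    max_per_protein = int(per_protein.max())
    return {
        "selected_cutoff": cutoff,
        "tpr": tpr,
        "fpr": fpr,
        "auc": auc(roc),
        "n_detections": len(detections),
        "n_known_detected": counts.tp,
        "n_novel": len(novel),
        "mean_similarity_detected": summary["mean_similarity"],
        "n_novel_allosteric": novel_allosteric,
        "n_proteins_without_detection": int((per_protein == 0).sum()),
        "n_metabolites_without_detection": int((per_metabolite == 0).sum()),
        "max_detections_per_protein": max_per_protein,
        "most_connected_proteins": sorted(
            per_protein.index[per_protein == max_per_protein]
        ),
    }
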