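"""Binding-mode classification and network summary statistics.

A detected interactor that is chemically similar to the substrates or
products of its target enzyme most plausibly binds at the active site
(competitive candidate); a dissimilar one points to a separate, allosteric
site.  The proxy is the maximum global chemical similarity between the
metabolite and the enzyme's reactants, thresholded at 0.5: strictly below
0.5 is allosteric, at or above is competitive, and pairs without a score
stay unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tables import ReferenceSet, SimilarityTable

SIMILARITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class ClassifiedInteraction:
    protein_id: str
    metabolite_id: str
    delta_rf: float
    known: bool
    known_type: str | None
    max_similarity: float | None
    mode: str  # allosteric_candidate | competitive_candidate | unclassified


def classify_binding_mode(
    detections,
    similarity: SimilarityTable,
    reference: ReferenceSet | None = None,
    threshold: float = SIMILARITY_THRESHOLD,
) -> list:
    """Label every detection as allosteric or competitive candidate.

    ``detections`` is an iterable of (protein_id, metabolite_id, delta_rf).
    Similarity strictly below the threshold means allosteric candidate;
    at or above, competitive candidate; a missing similarity leaves the
    pair unclassified.
    """
    out = []
    for protein_id, metabolite_id, value in detections:
        sim = similarity.get(protein_id, metabolite_id)
        if sim is None:
            mode = "unclassified"
        elif sim < threshold:
            mode = "allosteric_candidate"
        else:
            mode = "competitive_candidate"
        known_type = (
            reference.type_of(protein_id, metabolite_id) if reference is not None else None
        )
        out.append(
            ClassifiedInteraction(
                protein_id=protein_id,
                metabolite_id=metabolite_id,
                delta_rf=float(value),
                known=known_type is not None,
                known_type=known_type,
                max_similarity=sim,
                mode=mode,
            )
        )
    return out


def classification_summary(classified) -> dict:
    """Counts per mode plus the mean similarity over scored detections."""
    classified = list(classified)
    counts = {
        mode: sum(1 for c in classified if c.mode == mode)
        for mode in ("allosteric_candidate", "competitive_candidate", "unclassified")
    }
    sims = [c.max_similarity for c in classified if c.max_similarity is not None]
    return {
        "n_detections": len(classified),
        **counts,
        "mean_similarity": float(np.mean(sims)) if sims else None,
    }


# ----------------------------------------------------------------------


def pathway_summary(
    detections,
    pathway_of: dict,
    reference: ReferenceSet | None = None,
    exclude_catalytic: bool = False,
) -> dict:
    """Mean interactions per enzyme, by pathway.

    ``detections`` is an iterable of (protein_id, metabolite_id[, ...]);
    ``pathway_of`` must annotate every protein (proteins with zero
    detections still enter their pathway's denominator).  With
    ``exclude_catalytic``, detections whose reference type is purely
    catalytic are dropped before counting; pairs known as both catalytic and
    regulatory are retained as regulatory.
    """
    counts: dict = {p: 0 for p in pathway_of}
    kept = 0
    for det in detections:
        protein_id, metabolite_id = det[0], det[1]
        if protein_id not in pathway_of:
            raise ValueError(f"protein {protein_id!r} has no pathway annotation")
        if exclude_catalytic and reference is not None:
            if reference.type_of(protein_id, metabolite_id) == "catalytic":
                continue
        counts[protein_id] += 1
        kept += 1
    groups: dict = {}
    for protein_id, pw in pathway_of.items():
        groups.setdefault(pw, []).append(counts[protein_id])
    return {
        "per_protein": counts,
        "per_pathway_mean": {pw: float(np.mean(v)) for pw, v in sorted(groups.items())},
        "per_pathway_n": {pw: len(v) for pw, v in sorted(groups.items())},
        "per_pathway_counts": {pw: v for pw, v in sorted(groups.items())},
        "n_detections_counted": kept,
    }


def welch_t_test(group_a, group_b, tails: str = "two") -> tuple[float, float]:
    """Welch's unequal-variance t-test between two count vectors.

    Uses the Welch-Satterthwaite degrees of freedom; ``tails='one'`` tests
    the alternative mean(a) > mean(b).  Each group needs at least two values
    and the pooled data must carry some variance.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must be finite")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    alternative = {"two": "two-sided", "one": "greater"}[tails]
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def correlate_counts(x, y) -> float:
    """Squared Pearson correlation between two equal-length vectors."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
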