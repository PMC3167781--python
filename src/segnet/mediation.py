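"""Regression-residual test of transcript-mediated protein regulation.

For a protein with a significant locus linkage, the protein trait is
regressed (OLS) on the gene's own transcript trait and the residuals are
re-tested for linkage to the same locus.  A linkage that disappears
(residual p >= alpha) is labelled transcript_mediated: the locus evidently
controls the protein *through* the transcript.  A linkage that survives is
not_transcript_mediated.  This is the loss-of-significance rule, not a
formal mediation estimator; partial attenuation is visible in the reported
-log10 p pairs but receives no label of its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from segnet.types import ConstantTraitError
from segnet.linkage import marker_t_test

TRANSCRIPT_MEDIATED = "transcript_mediated"
NOT_TRANSCRIPT_MEDIATED = "not_transcript_mediated"


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    residuals: np.ndarray
    degenerate: bool = False  # all-zero residuals (perfect collinearity)


def regress_protein_on_transcript(protein: np.ndarray, transcript: np.ndarray) -> RegressionFit:
    """OLS of protein on transcript; residuals carry the non-transcript part.

    Residuals sum to zero and are orthogonal to the transcript vector (the
    normal equations), which is what makes the residual linkage test a test
    of regulation beyond the transcript.
    """
    protein = np.asarray(protein, dtype=float)
    transcript = np.asarray(transcript, dtype=float)
    if protein.shape != transcript.shape or protein.ndim != 1:
        raise ValueError("protein and transcript must be 1-d vectors of equal length")
    if len(protein) < 3:
        raise ValueError("need at least 3 segregants for the regression")
    if np.ptp(transcript) == 0:
        raise ConstantTraitError("constant transcript vector; mediation test undefined")
    tc = transcript - transcript.mean()
    slope = float((tc @ (protein - protein.mean())) / (tc @ tc))
    intercept = float(protein.mean() - slope * transcript.mean())
    residuals = protein - (slope * transcript + intercept)
    degenerate = bool(np.allclose(residuals, 0.0, atol=1e-12 * max(1.0, np.abs(protein).max())))
    return RegressionFit(slope=slope, intercept=intercept, residuals=residuals, degenerate=degenerate)


def residual_linkage(fit: RegressionFit, marker: np.ndarray, equal_var: bool = False) -> tuple[float, float]:
    """Re-test linkage on regression residuals.

    Degenerate (all-zero) residuals return (t=0, p=1) so that pipelines on
    noiseless synthetic data complete instead of erroring.
    """
    if fit.degenerate:
        return 0.0, 1.0
    return marker_t_test(fit.residuals, marker, equal_var=equal_var)


def neglog10(p: float) -> float:
    """-log10 of a p-value in (0, 1]."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return -math.log10(p)


def classify_mediation(p_original: float, p_residual: float, alpha: float = 0.05) -> dict:
    """Label a significant protein linkage by whether regression kills it.

    Only linkages with p_original < 0.05 enter the test (those are the
    points on the residual-vs-original scatter); transcript_mediated iff
    the residual p rises to >= *alpha*.
    """
    if not p_original < 0.05:
        raise ValueError(
            f"p_original={p_original} is not below 0.05; linkage is not in the tested set"
        )
    label = TRANSCRIPT_MEDIATED if p_residual >= alpha else NOT_TRANSCRIPT_MEDIATED
    return {
        "p_original": p_original,
        "p_residual": p_residual,
        "neglog_p_original": neglog10(p_original),
        "neglog_p_residual": neglog10(p_residual),
        "label": label,
    }


def mediation_table(
    proteins,
    transcripts,
    genotypes,
    linkage_records,
    alpha: float = 0.05,
    equal_var: bool = False,
):
    """Run the full residual test for every significant protein linkage peak.

    *linkage_records* is a linkage table (see
    :func:`segnet.linkage.permutation_fdr`); one mediation record is
    produced per locus peak with p_original < 0.05.  Returns a DataFrame
    with gene, marker, slope, intercept, p_original, p_residual, both
    -log10 p values and the label.
    """
    import pandas as pd

    peaks = linkage_records[
        (linkage_records["fdr_tier"] != "none")
        & linkage_records.get("is_peak", True)
        & (linkage_records["p"] < 0.05)
    ]
    rows = []
    for _, rec in peaks.iterrows():
        gene = rec["trait"]
        prot = proteins.gene_values(gene)
        trans = transcripts.gene_values(gene)
        marker = genotypes.marker_calls(rec["marker"])
        fit = regress_protein_on_transcript(prot, trans)
        t_res, p_res = residual_linkage(fit, marker, equal_var=equal_var)
        rec_out = classify_mediation(float(rec["p"]), p_res, alpha=alpha)
        rows.append(
            {
                "gene": gene,
                "marker": rec["marker"],
                "locus_id": rec["locus_id"],
                "slope": fit.slope,
                "intercept": fit.intercept,
                "t_residual": t_res,
                **rec_out,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "marker", "locus_id", "slope", "intercept", "t_residual",
            "p_original", "p_residual", "neglog_p_original", "neglog_p_residual", "label",
        ],
    )
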