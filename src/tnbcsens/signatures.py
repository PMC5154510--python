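"""Mutational-signature deconvolution by non-negative least squares.

Each tumor's substitutions are tallied over the 96 trinucleotide contexts
and the resulting count vector, normalized to a probability vector, is
decomposed over a reference loading matrix L (96 x K, columns summing to
one) by solving  min ||x - L c||_2  subject to c >= 0  with the
Lawson-Hanson active-set algorithm. Normalized coefficients are the
estimated signature proportions; the signature with the greatest
coefficient is the dominant signature (ties broken by reference column
order and flagged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .contexts import CONTEXTS_96, CONTEXT_INDEX
from .models import MutationRecord, SignatureReference

logger = logging.getLogger(__name__)

#: Below this many contexted mutations a fit is flagged low-confidence.
LOW_CONFIDENCE_MIN_MUTATIONS = 20


class FitUnavailableError(ValueError):
    pass


@dataclass(frozen=True)
class SignatureFit:
    sample_id: str
    signatures: tuple[str, ...]
    coefficients: tuple[float, ...]
    proportions: tuple[float, ...]
    dominant: str
    dominant_tie: bool
    residual_norm: float
    n_contexted: int
    low_confidence: bool


def context_counts(mutations: list[MutationRecord]) -> np.ndarray:
    """Tally substitutions into the canonical 96-context vector.

    Records without a context label are skipped (count logged); an unknown
    label raises. Indels carry no substitution context and are skipped the
    same way.
    """
    counts = np.zeros(96, dtype=int)
    skipped = 0
    for m in mutations:
        if m.trinucleotide_context is None:
            skipped += 1
            continue
        try:
            counts[CONTEXT_INDEX[m.trinucleotide_context]] += 1
        except KeyError:
            raise ValueError(
                f"unknown trinucleotide context label: {m.trinucleotide_context!r}"
            ) from None
    if skipped:
        logger.info("context_counts: skipped %d records without context", skipped)
    return counts


def fit_signatures(
    counts: np.ndarray,
    reference: SignatureReference,
    sample_id: str = "",
) -> SignatureFit:
    """NNLS decomposition of a context-count vector over reference signatures."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise FitUnavailableError(f"{sample_id}: zero context counts, cannot fit")
    x = counts / total
    coef, residual = nnls(reference.matrix, x)
    csum = coef.sum()
    proportions = coef / csum if csum > 0 else np.zeros_like(coef)
    label, tie = argmax_with_tie(proportions, reference.signatures)
    return SignatureFit(
        sample_id=sample_id,
        signatures=tuple(reference.signatures),
        coefficients=tuple(float(c) for c in coef),
        proportions=tuple(float(p) for p in proportions),
        dominant=label,
        dominant_tie=tie,
        residual_norm=float(residual),
        n_contexted=int(total),
        low_confidence=bool(total < LOW_CONFIDENCE_MIN_MUTATIONS),
    )


def argmax_with_tie(proportions, labels) -> tuple[str, bool]:
    """First label attaining the maximum proportion, with an exact-tie flag."""
    proportions = np.asarray(proportions, dtype=float)
    idx = int(np.argmax(proportions))
    tie = bool((proportions == proportions[idx]).sum() > 1)
    return labels[idx], tie


def dominant_signature(fit: SignatureFit) -> str:
    """Label of the maximal proportion (first of any exact tie)."""
    return fit.dominant


def synthetic_signature_reference() -> SignatureReference:
    """A synthetic four-signature reference with distinct, realistic shapes.

    This is a synthetic stand-in constructed for simulation and testing:
    it is NOT a published signature catalog. The four columns emulate the
    qualitative shapes of processes active in breast cancer:

    * ``age`` — C>T concentrated at NpCpG contexts (spontaneous deamination
      of methylated cytosine);
    * ``APOBEC`` — C>T and C>G at TpCpN contexts;
    * ``BRCA`` — near-uniform mass across all 96 contexts, the flat profile
      of homologous-recombination deficiency;
    * ``MMR`` — C>T enriched at NpCpG plus elevated T>C, loosely mimicking
      mismatch-repair deficiency.

    Deterministic: no randomness is involved.
    """
    data = {}
    age = np.full(96, 0.05)
    apobec = np.full(96, 0.02)
    brca = np.full(96, 1.0)
    mmr = np.full(96, 0.05)
    for i, label in enumerate(CONTEXTS_96):
        five, ref, alt, three = label[0], label[2], label[4], label[6]
        sub = f"{ref}>{alt}"
        if sub == "C>T" and three == "G":
            age[i] = 10.0
            mmr[i] = 5.0
        if five == "T" and sub in ("C>T", "C>G"):
            apobec[i] = 8.0
        if sub == "T>C":
            mmr[i] += 2.0
    data["age"] = age
    data["APOBEC"] = apobec
    data["BRCA"] = brca
    data["MMR"] = mmr
    loadings = pd.DataFrame(data, index=list(CONTEXTS_96))
    return SignatureReference(loadings)


def fit_table(fits: list[SignatureFit]) -> pd.DataFrame:
    """Per-sample signature-proportion table (one row per fit)."""
    rows = []
    for f in fits:
        row = {"sample_id": f.sample_id}
        row.update({s: p for s, p in zip(f.signatures, f.proportions)})
        row.update(
            dominant=f.dominant,
            residual_norm=f.residual_norm,
            n_contexted=f.n_contexted,
            low_confidence=int(f.low_confidence),
        )
        rows.append(row)
    return pd.DataFrame(rows)
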