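"""qPCR relative quantification.

RT-qPCR fold changes by the delta-delta-Ct method with one or more reference
genes (references combined by the arithmetic mean of their mean Cts, i.e. the
geometric mean on the expression scale), and ChIP-qPCR fold enrichment of a
positive region over the mean percent input of two negative control regions.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["ddct_fold_change", "percent_input", "chip_qpcr_enrichment"]


def _mean_ct(values) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty Ct replicate list")
    if (arr <= 0).any():
        raise ValueError("Ct values must be > 0")
    return float(arr.mean())


def ddct_fold_change(
    target_cts: dict[str, list[float]],
    reference_cts: dict[str, dict[str, list[float]]],
    control: str = "control",
) -> dict[str, float]:
    """Fold change of each condition versus the control by delta-delta Ct.

    ``target_cts`` maps condition -> Ct replicates for the gene of interest;
    ``reference_cts`` maps reference gene -> condition -> Ct replicates.
    Per condition, dCt = mean target Ct - mean over references of the mean
    reference Ct; fold = 2**-(dCt_condition - dCt_control). The control maps
    to exactly 1.
    """
    if control not in target_cts:
        raise ValueError(f"control condition {control!r} missing from target Cts")
    if not reference_cts:
        raise ValueError("at least one reference gene required")
    dct = {}
    for condition, cts in target_cts.items():
        ref_means = []
        for gene, per_condition in reference_cts.items():
            if condition not in per_condition:
                raise ValueError(f"reference {gene!r} missing condition {condition!r}")
            ref_means.append(_mean_ct(per_condition[condition]))
        dct[condition] = _mean_ct(cts) - float(np.mean(ref_means))
    return {
        condition: 2.0 ** -(d - dct[control]) for condition, d in dct.items()
    }


def percent_input(ct_input: float, ct_ip: float, input_percent: float = 1.0) -> float:
    """Percent input from input and IP Cts, correcting for the input dilution.

    The input Ct is shifted by log2(100 / input_percent) so it represents the
    undiluted chromatin, then %input = 100 * 2**(adjusted input Ct - IP Ct).
    """
    if input_percent <= 0 or input_percent > 100:
        raise ValueError("input_percent must be in (0, 100]")
    adjusted = ct_input - math.log2(100.0 / input_percent)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def chip_qpcr_enrichment(
    positive_percent_input: float,
    negative_percent_inputs: tuple[float, float],
) -> float:
    """Fold enrichment of the positive region over the mean of two negatives."""
    neg = np.asarray(negative_percent_inputs, dtype=float)
    if positive_percent_input <= 0 or (neg <= 0).any():
        raise ValueError("percent-input values must be > 0")
    if neg.size != 2:
        raise ValueError("exactly two negative regions expected")
    return float(positive_percent_input / neg.mean())
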