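"""Recovery and clustering evaluation measures.

Four scores cover the evaluation needs: chance-corrected partition
agreement (adjusted Rand index), entrywise genotype error rate,
the fraction of missing entries imputed to the correct state, and the
ratio of output to input genotype errors (FP + FN) over observed
positions.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .rpca import ObservedMatrix

__all__ = ["ari", "error_rate", "missing_imputed_rate", "fp_fn_ratio"]


def ari(labels_a, labels_b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    Symmetric, invariant to label permutation; 1 for identical
    partitions, about 0 for independent ones.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 points")
    return float(adjusted_rand_score(a, b))


def error_rate(recovered: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Fraction of entries where ``recovered != truth``.

    With ``mask`` given, only positions where ``mask`` is True are
    scored (observed-entry error rate); by default all entries count.
    """
    recovered = np.asarray(recovered)
    truth = np.asarray(truth)
    if recovered.shape != truth.shape:
        raise ValueError("shape mismatch")
    diff = recovered != truth
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask selects no entries")
        return float(diff[mask].mean())
    return float(diff.mean())


def missing_imputed_rate(recovered: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of unobserved (mask=False) entries imputed to the true state."""
    recovered = np.asarray(recovered)
    truth = np.asarray(truth)
    mask = np.asarray(mask, dtype=bool)
    if recovered.shape != truth.shape or mask.shape != truth.shape:
        raise ValueError("shape mismatch")
    missing = ~mask
    if not missing.any():
        raise ValueError("mask has no missing entries to score")
    return float((recovered[missing] == truth[missing]).mean())


def fp_fn_ratio(output: np.ndarray, input_obs: ObservedMatrix | np.ndarray, truth: np.ndarray,
                mask: np.ndarray | None = None) -> float:
    """Output/input ratio of genotype errors (FP + FN) over observed entries.

    Any miscalled entry counts one error: a non-reference call where the
    truth is reference is a false positive, a reference call where the
    truth is non-reference a false negative, and a wrong non-reference
    state one combined FP+FN.  0 means the output is error-free; 1 means
    it is no better than the raw input.
    """
    if isinstance(input_obs, ObservedMatrix):
        mask = input_obs.mask if mask is None else np.asarray(mask, dtype=bool)
        X_in = input_obs.X
    else:
        X_in = np.asarray(input_obs)
        mask = np.ones(X_in.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    output = np.asarray(output)
    truth = np.asarray(truth)
    n_out = int((output[mask] != truth[mask]).sum())
    n_in = int((X_in[mask] != truth[mask]).sum())
    if n_out == 0:
        return 0.0
    if n_in == 0:
        warnings.warn("input has no errors over observed entries; ratio undefined", stacklevel=2)
        return float("inf")
    return n_out / n_in
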