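"""Pedigree-based additive genetic relationship matrix A and its inverse.

The additive relationship matrix (numerator relationship matrix) holds
twice the kinship coefficient between every pair of pedigree members; it
parameterises the covariance of polygenic effects, a ~ N(0, A sigma2_a).
A is built by the tabular method, the inverse directly by the
Henderson/Quaas rules with full accounting for parental inbreeding.
"""

from __future__ import annotations

import numpy as np

from .io import Pedigree


def additive_relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Tabular method: A_ii = 1 + A_sd/2, A_ij = (A_js + A_jd)/2 for j < i.

    Requires the pedigree in topological order (Pedigree construction
    guarantees this).  Unknown-parent terms contribute 0.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        si, di = s[i], d[i]
        if si >= i or di >= i:
            raise ValueError("pedigree not topologically ordered")
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    return A


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """F_i = A_ii - 1; founders have F = 0."""
    return np.diag(additive_relationship_matrix(ped)) - 1.0


def inverse_relationship_matrix(ped: Pedigree) -> np.ndarray:
    """A^-1 assembled directly by the Henderson rules with Quaas's
    inbreeding adjustment.

    For individual i with parents s, d the Mendelian-sampling variance is

        d_i = 0.5 - 0.25 (F_s + F_d)        both parents known
        d_i = 0.75 - 0.25 F_p               one parent known
        d_i = 1                             founder

    and A^-1 accumulates alpha_i = 1/d_i over the (i, s, d) triplet.
    """
    n = len(ped)
    F = inbreeding_coefficients(ped)
    Ainv = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            dii = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            dii = 0.75 - 0.25 * F[max(si, di)]
        else:
            dii = 1.0
        if dii <= 0:
            raise np.linalg.LinAlgError(
                f"non-positive Mendelian sampling variance at {ped.ids[i]}")
        a = 1.0 / dii
        Ainv[i, i] += a
        for p in (si, di):
            if p >= 0:
                Ainv[i, p] -= a / 2.0
                Ainv[p, i] -= a / 2.0
        for p in (si, di):
            for q in (si, di):
                if p >= 0 and q >= 0:
                    Ainv[p, q] += a / 4.0
    return Ainv


def kinship_coefficient(ped: Pedigree, i: int, j: int,
                        _memo: dict | None = None) -> float:
    """Recursive coancestry oracle, independent of the tabular method.

    theta(i, j) = (theta(s_j, i) + theta(d_j, i)) / 2 for j not an ancestor
    of i, with theta(i, i) = (1 + F_i)/2 resolved through the same
    recursion.  Used only for cross-checking A (A_ij = 2 theta_ij).
    """
    if _memo is None:
        _memo = {}
    if i < 0 or j < 0:
        return 0.0
    key = (i, j) if i >= j else (j, i)
    if key in _memo:
        return _memo[key]
    a, b = key  # a >= b, so in topological order b is never a descendant of a
    if a == b:
        sa, da = ped.sire_idx[a], ped.dam_idx[a]
        val = 0.5 * (1.0 + kinship_coefficient(ped, sa, da, _memo))
    else:
        sa, da = ped.sire_idx[a], ped.dam_idx[a]
        val = 0.5 * (kinship_coefficient(ped, sa, b, _memo)
                     + kinship_coefficient(ped, da, b, _memo))
    _memo[key] = val
    return val


def relationship_matrix_recursive(ped: Pedigree) -> np.ndarray:
    """A via the coancestry recursion (oracle path for tests)."""
    n = len(ped)
    memo: dict = {}
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            A[i, j] = A[j, i] = 2.0 * kinship_coefficient(ped, i, j, memo)
    return A
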