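"""Free and bioavailable testosterone from total testosterone, SHBG and albumin.

Circulating testosterone partitions into a free fraction, a loosely
albumin-bound fraction and a tightly SHBG-bound fraction.  The free
concentration FT solves the two-binding-site mass balance

    T = FT * (1 + k*A) + S * FT / (1 + FT)

where T is total testosterone (nM), S is SHBG (nM), A is albumin (g/L) and
``k = 0.5217`` folds the albumin association constant into per-gram units.
Albumin binding is linear in FT (albumin is far from saturation at
physiological testosterone), SHBG binding is saturable with unit affinity on
the nM scale.  The mass balance is a quadratic in FT whose positive root is
the closed form implemented by :func:`free_testosterone`.  Bioavailable
testosterone is the free plus albumin-bound pool, ``BAT = FT * (1 + k*A)``.

Units are enforced at the interface (nM, g/L); the constant 0.5217 is
unit-specific, so no automatic conversion is attempted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ALBUMIN_K",
    "DETECTION_FLOOR_NM",
    "free_testosterone",
    "bioavailable_testosterone",
    "total_from_free",
    "apply_detection_floor",
    "derive_panel",
]

#: Albumin binding constant on the (nM testosterone, g/L albumin) scale.
ALBUMIN_K = 0.5217

#: Minimum detectable total testosterone of the assay, nM.
DETECTION_FLOOR_NM = 0.35

# Tolerance for clipping tiny negative floating-point residue in FT.
_CLIP_TOL = 1e-12


def _validate_nonneg(name: str, value: np.ndarray) -> None:
    if not np.all(np.isfinite(value) | np.isnan(value)):
        raise ValueError(f"{name} must be finite")
    if np.any(value < 0):
        raise ValueError(f"{name} must be non-negative")


def free_testosterone(total, shbg, albumin):
    """Free testosterone (nM) from total testosterone, SHBG and albumin.

    Parameters
    ----------
    total : array_like
        Total testosterone, nM.
    shbg : array_like
        Sex hormone binding globulin, nM.
    albumin : array_like
        Albumin, g/L.

    Returns
    -------
    ndarray or float
        Free testosterone in nM, clipped to ``[0, total]``.  NaN inputs
        propagate to NaN outputs.
    """
    T = np.asarray(total, dtype=float)
    S = np.asarray(shbg, dtype=float)
    A = np.asarray(albumin, dtype=float)
    scalar = T.ndim == 0 and S.ndim == 0 and A.ndim == 0
    T, S, A = np.atleast_1d(T), np.atleast_1d(S), np.atleast_1d(A)
    for name, v in (("total", T), ("shbg", S), ("albumin", A)):
        _validate_nonneg(name, v)

    c = ALBUMIN_K * A
    d = c + 1.0
    disc = (c + 1.0 + S - T) ** 2 + 4.0 * T * d
    # disc >= (c+1+S-T)^2 and 4*T*d >= 0, so it cannot go negative for valid
    # inputs; assert rather than raise.
    assert np.all(disc >= 0.0) or np.any(np.isnan(disc)), "negative discriminant"
    ft = (T - c - S - 1.0 + np.sqrt(disc)) / (2.0 * d)
    # guard floating-point residue at extreme inputs
    ft = np.where((ft < 0) & (ft > -_CLIP_TOL), 0.0, ft)
    ft = np.clip(ft, 0.0, T)
    return float(ft[0]) if scalar else ft


def bioavailable_testosterone(free, albumin):
    """Bioavailable testosterone ``BAT = FT * (1 + 0.5217 * A)`` (nM)."""
    ft = np.asarray(free, dtype=float)
    A = np.asarray(albumin, dtype=float)
    scalar = ft.ndim == 0 and A.ndim == 0
    ft, A = np.atleast_1d(ft), np.atleast_1d(A)
    _validate_nonneg("free", ft)
    _validate_nonneg("albumin", A)
    bat = ft * (1.0 + ALBUMIN_K * A)
    return float(bat[0]) if scalar else bat


def total_from_free(free, shbg, albumin):
    """Total testosterone implied by a free concentration (inverse mass balance).

    ``T = FT * (1 + k*A) + S * FT / (1 + FT)`` — exact inverse of
    :func:`free_testosterone`, used by the cohort simulator to manufacture
    assay values consistent with a target bioavailable level.
    """
    ft = np.asarray(free, dtype=float)
    S = np.asarray(shbg, dtype=float)
    A = np.asarray(albumin, dtype=float)
    scalar = ft.ndim == 0 and S.ndim == 0 and A.ndim == 0
    ft, S, A = np.atleast_1d(ft), np.atleast_1d(S), np.atleast_1d(A)
    _validate_nonneg("free", ft)
    _validate_nonneg("shbg", S)
    _validate_nonneg("albumin", A)
    T = ft * (1.0 + ALBUMIN_K * A) + S * ft / (1.0 + ft)
    return float(T[0]) if scalar else T


def apply_detection_floor(values, floor: float = DETECTION_FLOOR_NM):
    """Replace values below the assay detection limit with the limit itself.

    Returns ``(floored_values, n_replaced)``.  NaN values are left as NaN and
    not counted.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    v = np.asarray(values, dtype=float)
    below = v < floor  # NaN compares False
    out = np.where(below, floor, v)
    return out, int(below.sum())


def derive_panel(
    pheno,
    total_col: str = "total_testosterone",
    shbg_col: str = "shbg",
    albumin_col: str = "albumin",
    floor: float = DETECTION_FLOOR_NM,
    free_col: str = "free_testosterone",
    bioavailable_col: str = "bioavailable_testosterone",
):
    """Add derived free/bioavailable testosterone columns to a phenotype table.

    The detection floor is applied to the *measured* total testosterone before
    derivation, mirroring how assay values below the limit are coded at the
    limit.  The floored total is written back to ``total_col``.

    Returns ``(pheno, n_floored)``; ``pheno`` is modified in place.
    """
    total, n_floored = apply_detection_floor(pheno[total_col].to_numpy(float), floor)
    pheno[total_col] = total
    ft = free_testosterone(total, pheno[shbg_col].to_numpy(float), pheno[albumin_col].to_numpy(float))
    pheno[free_col] = ft
    pheno[bioavailable_col] = bioavailable_testosterone(ft, pheno[albumin_col].to_numpy(float))
    return pheno, n_floored
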