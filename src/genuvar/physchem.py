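"""Grantham physicochemical distance between amino acids.

The Grantham distance combines three side-chain properties — composition
``c`` (atomic weight ratio of non-carbon elements in end groups), polarity
``p`` and molecular volume ``v`` — into a single dissimilarity

.. math::

    D_{ij} = \\rho \\left[ \\alpha (c_i - c_j)^2 + \\beta (p_i - p_j)^2
             + \\gamma (v_i - v_j)^2 \\right]^{1/2}

with weights chosen so that each property contributes equally on average
and the global scale :math:`\\rho` set so the mean over all 190 amino-acid
pairs is 100 (Grantham, Science 185:862, 1974).  Large scores flag
physicochemically radical substitutions: Asp→Ala scores 126, while the
conservative Ile→Thr scores 89.
"""

from __future__ import annotations

import itertools
import math

import pandas as pd

from .coordinates import one_letter

__all__ = ["grantham", "grantham_matrix", "AMINO_ACIDS"]

#: Property table from Grantham (1974), keyed by one-letter code:
#: (composition c, polarity p, molecular volume v).
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.00, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.00, 8.1, 31.0),
    "V": (0.00, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.00, 5.2, 111.0),
    "F": (0.00, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.00, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

ALPHA = 1.833
BETA = 0.1018
GAMMA = 0.000399
RHO = 50.723

AMINO_ACIDS: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")


def _round_half_away(x: float) -> int:
    # published matrices round half away from zero
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def grantham(aa1: str, aa2: str, *, rounded: bool = True) -> float:
    """Grantham distance between two standard amino acids.

    Parameters
    ----------
    aa1, aa2:
        One- or three-letter amino-acid codes (case-insensitive).
    rounded:
        Return the conventionally reported integer score (default) or the
        raw floating-point distance.

    Returns
    -------
    The distance, symmetric in its arguments and zero on identity.

    Raises
    ------
    KeyError
        If either residue is not one of the 20 standard amino acids.
    """
    try:
        a = one_letter(aa1)
        b = one_letter(aa2)
    except ValueError:
        raise KeyError(
            f"nonstandard amino acid in pair ({aa1!r}, {aa2!r})"
        ) from None
    if a not in GRANTHAM_PROPERTIES or b not in GRANTHAM_PROPERTIES:
        raise KeyError(f"nonstandard amino acid in pair ({aa1!r}, {aa2!r})")
    c1, p1, v1 = GRANTHAM_PROPERTIES[a]
    c2, p2, v2 = GRANTHAM_PROPERTIES[b]
    d = RHO * math.sqrt(
        ALPHA * (c1 - c2) ** 2 + BETA * (p1 - p2) ** 2 + GAMMA * (v1 - v2) ** 2
    )
    return float(_round_half_away(d)) if rounded else d


def grantham_matrix(*, rounded: bool = True) -> pd.DataFrame:
    """Full 20x20 Grantham distance table.

    Symmetric with a zero diagonal; rows and columns are one-letter codes
    in the order of :data:`AMINO_ACIDS`.
    """
    df = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
    for a, b in itertools.combinations(AMINO_ACIDS, 2):
        d = grantham(a, b, rounded=rounded)
        df.loc[a, b] = d
        df.loc[b, a] = d
    return df
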