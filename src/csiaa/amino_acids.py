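"""Canonical amino-acid codes and their trophic/source grouping.

The thirteen amino acids routinely resolved by GC-IRMS of hydrolysed
particulate organic matter. "Asp" and "Glu" denote the acid + amide pools
(Asp + Asn, Glu + Gln), which co-elute after acid hydrolysis.

Grouping follows the standard food-web behaviour of δ¹⁵N:

* trophic amino acids (Tr-AA) are strongly ¹⁵N-enriched with each trophic
  transfer;
* source amino acids (Src-AA) retain the δ¹⁵N of the nitrogen source;
* Gly and Thr follow neither pattern and are kept apart.
"""

from __future__ import annotations

CANONICAL_AA: tuple[str, ...] = (
    "Ala", "Asp", "Glu", "Leu", "Ile", "Pro", "Val",
    "Gly", "Lys", "Ser", "Phe", "Tyr", "Thr",
)

TROPHIC_AA: frozenset[str] = frozenset({"Ala", "Val", "Leu", "Ile", "Pro", "Asp", "Glu"})
SOURCE_AA: frozenset[str] = frozenset({"Ser", "Phe", "Lys", "Tyr"})
OTHER_AA: frozenset[str] = frozenset({"Gly", "Thr"})

#: the seven amino acids entering the ΣV resynthesis index
SIGMA_V_AA: frozenset[str] = TROPHIC_AA

_BY_LOWER = {code.lower(): code for code in CANONICAL_AA}


def normalize_code(code: str) -> str:
    """Return the canonical 3-letter form of *code* (case-insensitive).

    Raises
    ------
    KeyError
        If *code* is not one of the thirteen canonical amino acids.
    """
    key = str(code).strip().lower()
    if key not in _BY_LOWER:
        raise KeyError(code)
    return _BY_LOWER[key]


def is_canonical(code: str) -> bool:
    return str(code).strip().lower() in _BY_LOWER
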