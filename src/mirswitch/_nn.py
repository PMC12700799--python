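"""RNA nearest-neighbor stacking free energies (Watson-Crick, 37 degC, kcal/mol).

Turner-2004-style helix propagation parameters (Xia et al. measurements).
A stack is written ``XY/WZ``: top strand 5'-XY-3', bottom strand 3'-WZ-5',
with X paired to W and Y paired to Z.  The ten unique values below are closed
under the strand-flip symmetry dG(XY/WZ) == dG(ZW/YX) to give all sixteen
Watson-Crick stack keys.  Wobble (G.U) pairs are treated as unpaired by the
energy model in this package (they contribute 0 and are flagged).
"""

from __future__ import annotations

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

_CANONICAL: dict[str, float] = {
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
}


def _flip(key: str) -> str:
    top, bottom = key.split("/")
    # reading the same stack from the other strand: top' = Z W, bottom' = Y X
    return bottom[1] + bottom[0] + "/" + top[1] + top[0]


STACK_DG: dict[str, float] = {}
for _k, _v in _CANONICAL.items():
    STACK_DG[_k] = _v
    STACK_DG.setdefault(_flip(_k), _v)


def is_watson_crick(a: str, b: str) -> bool:
    return WC_COMPLEMENT.get(a) == b


def stack_energy(top: str, bottom: str) -> float:
    """Free energy of one stack; ``top`` is 5'->3', ``bottom`` is its 3'->5' partner."""
    key = f"{top}/{bottom}"
    if key not in STACK_DG:
        raise KeyError(f"not a Watson-Crick stack: {key}")
    return STACK_DG[key]
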