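"""Element vocabulary shared by parsing, embedding, and the synthetic oracle."""

from __future__ import annotations

SYMBOL_TO_Z = {
    "H": 1, "HE": 2, "LI": 3, "BE": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "NE": 10, "NA": 11, "MG": 12, "AL": 13, "SI": 14, "P": 15,
    "S": 16, "CL": 17, "AR": 18, "K": 19, "CA": 20, "FE": 26, "ZN": 30,
    "BR": 35, "I": 53,
}
Z_TO_SYMBOL = {
    1: "H", 6: "C", 7: "N", 8: "O", 9: "F", 15: "P", 16: "S",
    17: "Cl", 35: "Br", 53: "I", 26: "Fe", 30: "Zn", 11: "Na",
    12: "Mg", 19: "K", 20: "Ca",
}

#: default vocabulary: organic subset + halogens
DEFAULT_VOCABULARY: tuple[int, ...] = (1, 6, 7, 8, 9, 15, 16, 17, 35, 53)


class VocabularyError(ValueError):
    """An element outside the configured vocabulary was encountered."""


def symbol_to_z(symbol: str) -> int:
    z = SYMBOL_TO_Z.get(symbol.strip().upper())
    if z is None:
        raise VocabularyError(f"unknown element symbol {symbol!r}")
    return z


def z_to_symbol(z: int) -> str:
    try:
        return Z_TO_SYMBOL[int(z)]
    except KeyError:
        raise VocabularyError(f"no symbol registered for Z={z}") from None


def check_vocabulary(zs, vocabulary=DEFAULT_VOCABULARY) -> None:
    """Raise VocabularyError if any atomic number is outside `vocabulary`."""
    vocab = set(int(v) for v in vocabulary)
    bad = sorted({int(z) for z in zs} - vocab)
    if bad:
        raise VocabularyError(
            f"elements Z={bad} are outside the configured vocabulary {sorted(vocab)}"
        )


def z_index_map(vocabulary=DEFAULT_VOCABULARY) -> dict[int, int]:
    """Map atomic number -> dense embedding index."""
    return {int(z): i for i, z in enumerate(vocabulary)}
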