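"""Canonical 96 trinucleotide substitution contexts (COSMIC convention).

Single-base substitutions are collapsed onto the pyrimidine reference
strand, giving six substitution types (C>A, C>G, C>T, T>A, T>C, T>G),
each observed in 4 x 4 flanking-base combinations: 96 context classes in
the standard ``5'[ref>alt]3'`` label format, e.g. ``A[C>T]G``.
"""

from __future__ import annotations

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

CONTEXT_INDEX: dict[str, int] = {c: i for i, c in enumerate(CONTEXTS_96)}


def parse_context(label: str) -> tuple[str, str, str, str]:
    """Split a context label into (5' base, ref, alt, 3' base)."""
    if len(label) != 7 or label[1] != "[" or label[3] != ">" or label[5] != "]":
        raise ValueError(f"malformed trinucleotide context label: {label!r}")
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    if any(b not in _BASES for b in (five, ref, alt)):
        raise ValueError(f"malformed trinucleotide context label: {label!r}")
    return five, ref, alt, three


def normalize_context(label: str) -> str:
    """Return the pyrimidine-strand representation of a context label.

    Purine-reference labels (ref A or G) are reverse-complemented onto the
    pyrimidine strand; pyrimidine-reference labels are returned unchanged.
    Raises ``ValueError`` for labels that are not one of the 192 strandwise
    possibilities.
    """
    five, ref, alt, three = parse_context(label)
    if ref == alt:
        raise ValueError(f"context with identical ref and alt: {label!r}")
    if ref in "CT":
        out = label
    else:
        out = (
            f"{_COMPLEMENT[three]}[{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}]"
            f"{_COMPLEMENT[five]}"
        )
    if out not in CONTEXT_INDEX:
        raise ValueError(f"unknown trinucleotide context label: {label!r}")
    return out
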