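"""96-class trinucleotide substitution contexts (SBS-96).

Single-base substitutions are binned into the standard 96 classes used by
mutational-signature analysis: six pyrimidine-centred substitution types
(C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 4 x 4 flanking bases.
Substitutions reported on the purine strand are mapped to their reverse
complement before binning, so a G>T call at 5'-T, 3'-G is counted in the
C[C>A]A class (the complement of the reported triplet read 3'->5').

The canonical ordering is the COSMIC one: substitution type varies slowest
(blocks of 16), then the 5' base, then the 3' base, both alphabetical.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six pyrimidine-normalized substitution types, canonical block order
SUBSTITUTION_TYPES: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)

N_CONTEXTS = 96


def context_label(index: int) -> str:
    """Return the COSMIC-style label (e.g. ``"A[C>A]A"``) for a class index."""
    if not 0 <= index < N_CONTEXTS:
        raise ValueError(f"context index out of range: {index}")
    sub, rem = divmod(index, 16)
    five, three = divmod(rem, 4)
    ref, alt = SUBSTITUTION_TYPES[sub]
    return f"{BASES[five]}[{ref}>{alt}]{BASES[three]}"


#: canonical 96 labels in canonical order
CONTEXT_LABELS: tuple[str, ...] = tuple(context_label(i) for i in range(N_CONTEXTS))

_LABEL_TO_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def context_index(label: str) -> int:
    """Inverse of :func:`context_label`; raises ``ValueError`` on bad labels."""
    try:
        return _LABEL_TO_INDEX[label.strip().upper()]
    except KeyError:
        raise ValueError(f"not a valid SBS-96 context label: {label!r}") from None


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def classify_substitution(ref: str, alt: str, five_prime: str, three_prime: str) -> int:
    """Map a substitution with its flanking bases to its SBS-96 class.

    Purine-reference substitutions are reverse-complemented first (the 5'
    flank of the purine strand becomes the 3' flank of the pyrimidine
    strand).  Raises ``ValueError`` for non-ACGT bases or ref == alt.
    """
    ref, alt = ref.upper(), alt.upper()
    five_prime, three_prime = five_prime.upper(), three_prime.upper()
    for b in (ref, alt, five_prime, three_prime):
        if b not in BASES:
            raise ValueError(f"ambiguous or invalid base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five_prime, three_prime = COMPLEMENT[three_prime], COMPLEMENT[five_prime]
    sub = SUBSTITUTION_TYPES.index((ref, alt))
    return sub * 16 + BASES.index(five_prime) * 4 + BASES.index(three_prime)


def parse_context_column(value: str) -> int:
    """Parse either a COSMIC label ("A[C>A]A") or an integer class 0-95."""
    value = value.strip()
    if value.isdigit() or (value.startswith("-") and value[1:].isdigit()):
        idx = int(value)
        if not 0 <= idx < N_CONTEXTS:
            raise ValueError(f"context class out of range: {idx}")
        return idx
    return context_index(value)


def decompose_label(label: str) -> tuple[str, str, str, str]:
    """Split a label into (five_prime, ref, alt, three_prime)."""
    idx = context_index(label)
    sub, rem = divmod(idx, 16)
    five, three = divmod(rem, 4)
    ref, alt = SUBSTITUTION_TYPES[sub]
    return BASES[five], ref, alt, BASES[three]


def count_contexts(context_classes) -> np.ndarray:
    """Bin an iterable of context classes (ints 0-95 or labels) into a 96-vector.

    Entries that are ``None`` or NaN are skipped (ambiguous-base mutations);
    the returned vector therefore sums to the number of usable mutations.
    """
    counts = np.zeros(N_CONTEXTS, dtype=np.int64)
    for c in context_classes:
        if c is None:
            continue
        if isinstance(c, float) and np.isnan(c):
            continue
        if isinstance(c, str):
            c = parse_context_column(c)
        counts[int(c)] += 1
    return counts
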