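"""The 96-channel trinucleotide substitution lexicon.

Single-base substitutions are collapsed onto the pyrimidine strand: a
mutation whose reference base is a purine is reverse-complemented together
with its flanking bases before binning. Channels are ordered in the
standard lexicon A[C>A]A ... T[T>G]T (substitution class major, 5' flank,
3' flank minor).
"""

from __future__ import annotations

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def channel_name(ref: str, alt: str, context: str) -> str:
    """Map an SNV with its trinucleotide context to its channel name.

    Parameters
    ----------
    ref, alt
        Single reference and alternate bases.
    context
        The three-base context centred on the mutated base; ``context[1]``
        must equal ``ref``.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref in "AG":  # purine reference: collapse to pyrimidine strand
        ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def channel_index(ref: str, alt: str, context: str) -> int:
    """Channel index (0..95) of an SNV in its trinucleotide context."""
    return CHANNEL_INDEX[channel_name(ref, alt, context)]


def parse_channel(name: str) -> tuple[str, str, str]:
    """Decompose a channel name into (ref, alt, context)."""
    five, rest = name[0], name[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, f"{five}{ref}{three}"
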