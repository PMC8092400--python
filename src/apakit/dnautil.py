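"""Small nucleotide-sequence helpers shared across the package."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def longest_run(seq: str, base: str) -> int:
    """Length of the longest run of `base` in `seq`."""
    best = cur = 0
    for c in seq:
        if c == base:
            cur += 1
            if cur > best:
                best = cur
        else:
            cur = 0
    return best


def wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(path, records, width: int = 60) -> None:
    """Write (name, sequence) pairs as a wrapped FASTA file."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{wrap_fasta(seq, width)}\n")
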