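"""Small DNA utilities shared across the package."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# IUPAC ambiguity codes beyond ACGT; rejected by default, optionally tolerated.
IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")

_BASE_TO_CODE = {b: i for i, b in enumerate(DNA_ALPHABET)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographically smaller of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def validate_dna(seq: str, name: str = "sequence", allow_ambiguous: bool = False) -> None:
    """Raise ValueError (with offending position) unless ``seq`` is A/C/G/T.

    With ``allow_ambiguous`` the IUPAC one-letter ambiguity codes are tolerated.
    """
    allowed = set(DNA_ALPHABET)
    if allow_ambiguous:
        allowed |= IUPAC_AMBIGUOUS
    for pos, base in enumerate(seq):
        if base.upper() not in allowed:
            raise ValueError(
                f"{name}: non-DNA character {base!r} at position {pos}"
            )


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random A/C/G/T string of the given length."""
    codes = rng.integers(0, 4, size=length)
    return "".join(DNA_ALPHABET[c] for c in codes)


def mutate_fraction(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute exactly round(fraction*len) positions with a different base.

    Used to build correlated fixture paralogs (e.g. cry variants at ~92 %
    identity, pat/bar analogues at ~60 %).
    """
    n = len(seq)
    n_mut = int(round(fraction * n))
    positions = rng.choice(n, size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in DNA_ALPHABET if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def add_substitution_errors(seqs: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    """Apply i.i.d. per-base substitution errors to a batch of sequences.

    Vectorised over the concatenation of all sequences; an erroneous base is
    replaced by one of the three alternatives uniformly.
    """
    if error_rate <= 0 or not seqs:
        return list(seqs)
    joined = "".join(seqs)
    arr = np.frombuffer(joined.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    idx = np.flatnonzero(hit)
    if idx.size:
        # map base -> code, add 1..3 mod 4 -> guaranteed different base
        lut = np.zeros(256, dtype=np.uint8)
        for b, c in _BASE_TO_CODE.items():
            lut[ord(b)] = c
        codes = lut[arr[idx]]
        shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
        new_codes = (codes + shift) % 4
        base_bytes = np.frombuffer(DNA_ALPHABET.encode("ascii"), dtype=np.uint8)
        arr[idx] = base_bytes[new_codes]
    out_str = arr.tobytes().decode("ascii")
    res = []
    off = 0
    for s in seqs:
        res.append(out_str[off : off + len(s)])
        off += len(s)
    return res
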