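"""Low-level nucleotide utilities shared across the package.

Sequences are handled internally as ``numpy.uint8`` arrays with the encoding
A=0, C=1, G=2, T=3; conversion to/from strings happens only at I/O
boundaries.  All randomness flows through explicit ``numpy.random.Generator``
instances.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# uint8 ASCII -> 2-bit code lookup (255 marks non-ACGT)
_DECODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _DECODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _DECODE[_b] = _i

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0..T=3).

    Raises ``ValueError`` on characters outside ACGT/acgt.
    """
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    arr = _DECODE[np.frombuffer(seq, dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = chr(bytes(seq)[int(np.argmax(arr > 3))])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    """Decode a uint8 base array back to an ACGT string."""
    return BASES[np.asarray(arr, dtype=np.uint8)].tobytes().decode("ascii")


def as_array(seq) -> np.ndarray:
    """Coerce str/bytes/array input to the internal uint8 representation."""
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    return encode(seq)


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[np.asarray(arr, dtype=np.uint8)][::-1]


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. random sequence with the given expected GC fraction."""
    if length <= 0:
        raise ValueError(f"sequence length must be positive, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must lie in [0, 1], got {gc}")
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def mutate(arr: np.ndarray, n_subs: int, rng: np.random.Generator,
           record: bool = False):
    """Apply ``n_subs`` substitutions in place (Jukes–Cantor-like: the new
    base is drawn uniformly from the three alternatives).

    Positions are drawn uniformly with replacement and de-duplicated, so the
    realised count can be marginally below ``n_subs`` (irrelevant at genomic
    scale, and the draw itself is Poisson upstream).  Returns the array, or
    ``(array, positions)`` when ``record`` is set.
    """
    if n_subs <= 0 or arr.size == 0:
        return (arr, np.empty(0, dtype=np.int64)) if record else arr
    pos = np.unique(rng.integers(0, arr.size, size=n_subs))
    shift = rng.integers(1, 4, size=pos.size).astype(np.uint8)
    arr[pos] = (arr[pos] + shift) % 4
    return (arr, pos) if record else arr


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed codes of all overlapping k-mers (k <= 31), vectorised."""
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n - k + 1, dtype=np.uint64)
    a = arr.astype(np.uint64)
    for j in range(k):
        out <<= np.uint64(2)
        out |= a[j:n - k + 1 + j]
    return out


def hamming_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of equal positions of two equal-length encoded sequences."""
    if a.size != b.size:
        raise ValueError("hamming_identity requires equal-length sequences")
    if a.size == 0:
        return 1.0
    return float(np.mean(a == b))


# ---------------------------------------------------------------------------
# Satellite monomer stand-ins
# ---------------------------------------------------------------------------

def default_knob_monomers() -> dict[str, str]:
    """Synthetic stand-in consensus monomers for the two maize knob satellite
    families (a 180-bp unit and the closely related 202-bp unit).

    These are fixed pseudo-random sequences generated from a frozen seed, NOT
    the biological knob180/TR-1 consensi; they give the annotation machinery a
    deterministic target.  Real consensus sequences can be supplied wherever a
    monomer dict is accepted.
    """
    rng = np.random.default_rng(180202)
    m180 = decode(random_sequence(180, 0.45, rng))
    # the 202-bp family is "closely related": the 180-mer plus a 22-bp block,
    # lightly diverged
    extra = decode(random_sequence(22, 0.45, rng))
    m202 = encode(m180[:90] + extra + m180[90:])
    mutate(m202, 10, rng)
    return {"knob180": m180, "tr1_202": decode(m202)}
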