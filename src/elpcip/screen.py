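"""Probe polymorphism screen: classify probes against two genome sequence sets.

A hit is an ungapped occurrence of the probe or its reverse complement,
with at most ``max_mismatch`` mismatches, on any sequence of a genome set.
Probes hitting both genotypes are unaffected by sequence-level
polymorphism; probes hitting only one side flag candidate polymorphic
positions on the array.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode, revcomp
from .io import FormatError

__all__ = ["ProbeHitClass", "count_hits", "classify_probe", "classify_probes", "screen_summary"]

STATUSES = ("both", "a_only", "b_only", "neither")


@dataclass(frozen=True)
class ProbeHitClass:
    """Hit classification of one probe against two genome sets."""

    probe_id: str
    status: str
    hits_a: int
    hits_b: int


def _encode_genome(sequences: Mapping[str, str]) -> list[np.ndarray]:
    out = []
    for seq in sequences.values():
        # genome sequences may carry rare non-ACGT letters; map them to a
        # sentinel that can never match a probe base
        arr = np.full(len(seq), 255, dtype=np.uint8)
        for i, b in enumerate("ACGT"):
            arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
        out.append(arr)
    return out


def count_hits(
    probe_seq: str, encoded_genome: list[np.ndarray], max_mismatch: int = 0
) -> int:
    """Number of positions where the probe or its reverse complement occurs.

    A position matched by both orientations (palindromic probe) counts once.
    """
    fwd = encode(probe_seq)
    rev = encode(revcomp(probe_seq))
    w = len(fwd)
    total = 0
    for arr in encoded_genome:
        if len(arr) < w:
            continue
        windows = sliding_window_view(arr, w)
        mm_f = (windows != fwd).sum(axis=1)
        mm_r = (windows != rev).sum(axis=1)
        total += int((np.minimum(mm_f, mm_r) <= max_mismatch).sum())
    return total


def classify_probe(
    probe_seq: str,
    genome_a: Mapping[str, str],
    genome_b: Mapping[str, str],
    max_mismatch: int = 0,
    probe_id: str = "probe",
) -> ProbeHitClass:
    """Classify one probe as hitting both genomes, one, or neither."""
    if len(probe_seq) < 8:
        raise ValueError("probe length must be >= 8")
    if not genome_a or not genome_b:
        raise FormatError("genome sequence sets must be non-empty")
    enc_a = _encode_genome(genome_a)
    enc_b = _encode_genome(genome_b)
    return _classify(probe_id, probe_seq, enc_a, enc_b, max_mismatch)


def _classify(
    probe_id: str,
    probe_seq: str,
    enc_a: list[np.ndarray],
    enc_b: list[np.ndarray],
    max_mismatch: int,
) -> ProbeHitClass:
    hits_a = count_hits(probe_seq, enc_a, max_mismatch)
    hits_b = count_hits(probe_seq, enc_b, max_mismatch)
    if hits_a and hits_b:
        status = "both"
    elif hits_a:
        status = "a_only"
    elif hits_b:
        status = "b_only"
    else:
        status = "neither"
    return ProbeHitClass(probe_id, status, hits_a, hits_b)


def classify_probes(
    probes: Mapping[str, str],
    genome_a: Mapping[str, str],
    genome_b: Mapping[str, str],
    max_mismatch: int = 0,
) -> list[ProbeHitClass]:
    """Classify many probes, encoding each genome once."""
    if not genome_a or not genome_b:
        raise FormatError("genome sequence sets must be non-empty")
    enc_a = _encode_genome(genome_a)
    enc_b = _encode_genome(genome_b)
    return [
        _classify(pid, seq, enc_a, enc_b, max_mismatch) for pid, seq in probes.items()
    ]


def screen_summary(classes: Iterable[ProbeHitClass]) -> dict[str, float]:
    """Fraction of probes in each hit class; fractions sum to 1."""
    classes = list(classes)
    if not classes:
        raise ValueError("cannot summarize an empty probe list")
    n = len(classes)
    return {s: sum(c.status == s for c in classes) / n for s in STATUSES}


def to_frame(classes: Iterable[ProbeHitClass]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"probe_id": c.probe_id, "status": c.status, "hits_a": c.hits_a, "hits_b": c.hits_b}
            for c in classes
        ]
    )
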