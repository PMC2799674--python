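"""De novo promoter motif discovery (seed-and-refine) and IUPAC element scanning.

The discovery algorithm mirrors the classic seed-driven word-enumeration
strategy: every w-mer of the highest-ranked sequences seeds a candidate
motif from all foreground w-mers within a mismatch radius, candidates are
scored by a maximum-a-posteriori-style criterion

    score = log2(n_sites) * (1/w) * sum_i sum_b f_ib * log2(f_ib / p_b)

with f_ib = (count_ib + 0.5) / (n_sites + 2) and background base
frequencies p_b, and the top candidates are refined by greedy single-site
additions/removals accepted only when the score increases.  The procedure
is fully deterministic: ties are broken lexicographically by consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seq import BASES, IUPAC, decode, encode, revcomp

__all__ = ["MotifModel", "motif_score", "find_motifs", "scan_iupac"]


@dataclass
class MotifModel:
    """A fixed-width motif: count matrix, sites and MAP-style score."""

    width: int
    counts: np.ndarray                      # (4, width) site counts, ACGT rows
    sites: list[tuple[str, int, str]]       # (sequence id, offset, strand)
    score: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (4, self.width):
            raise ValueError("count matrix must be 4 x width")
        if self.n_sites < 2:
            raise ValueError("a motif needs at least 2 sites")
        if not np.allclose(self.counts.sum(axis=0), self.n_sites):
            raise ValueError("every column must sum to the number of sites")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))


def _score_from_counts(
    counts: np.ndarray, n_sites: np.ndarray | int, background: np.ndarray
) -> np.ndarray:
    """Vectorized score; counts has shape (..., 4, w)."""
    n = np.asarray(n_sites, dtype=float)
    f = (counts + 0.5) / (n[..., None, None] + 2.0)
    rel_ent = (f * np.log2(f / background[:, None])).sum(axis=(-2, -1)) / counts.shape[-1]
    return np.log2(n) * rel_ent


def motif_score(m: MotifModel, background: Sequence[float] | None = None) -> float:
    """MAP-style score of a motif under 0-order background frequencies."""
    bg = _check_background(background)
    if m.n_sites < 2:
        raise ValueError("a motif needs at least 2 sites")
    return float(_score_from_counts(m.counts, m.n_sites, bg))


def _check_background(background: Sequence[float] | None) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    return bg


def background_frequencies(sequences: Mapping[str, str]) -> np.ndarray:
    """0-order ACGT frequencies of a sequence set."""
    counts = np.zeros(4)
    for seq in sequences.values():
        for i, b in enumerate(BASES):
            counts[i] += seq.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _all_wmers(sequences: Mapping[str, str], w: int):
    """Every w-mer of every sequence on both strands.

    Returns (matrix of encoded w-mers, one-hot tensor, site tuples).
    Windows containing non-ACGT letters are skipped.
    """
    rows, sites = [], []
    for name, seq in sequences.items():
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(s) - w + 1):
                word = s[i : i + w]
                if any(b not in "ACGT" for b in word):
                    continue
                offset = i if strand == "+" else len(seq) - w - i
                rows.append(encode(word))
                sites.append((name, offset, strand))
    if not rows:
        raise ValueError("no valid w-mers in the sequence set")
    W = np.vstack(rows)
    onehot = np.zeros((len(rows), 4, w))
    onehot[np.arange(len(rows))[:, None], W, np.arange(w)] = 1.0
    return W, onehot, sites


def _refine(
    site_idx: list[int],
    onehot: np.ndarray,
    background: np.ndarray,
    max_iter: int = 100,
    words: np.ndarray | None = None,
) -> list[int]:
    """Greedy add/remove of single sites, accepted only on strict score increase.

    Uses the identity relent = [S - T]/(n+2) - w*log2(n+2) with
    S = sum phi(c+0.5), phi(x) = x*log2(x), T = sum (c+0.5)*log2(p_b), so a
    single-site move only touches the w incremented/decremented cells.
    """
    site_idx = list(site_idx)
    n_total, _four, w = onehot.shape
    if words is None:
        words = np.argmax(onehot, axis=1).astype(np.intp)  # (n_total, w)
    logbg = np.log2(background)
    word_bg = logbg[words].sum(axis=1)  # T shift of adding/removing each word
    cols = np.arange(w)

    def phi(x):
        return x * np.log2(x)

    def total_score(S, T, n):
        return np.log2(n) * ((S - T) / (n + 2.0) - w * np.log2(n + 2.0)) / w

    counts = onehot[site_idx].sum(axis=0)
    n = len(site_idx)
    S = phi(counts + 0.5).sum()
    T = ((counts + 0.5) * logbg[:, None]).sum()
    for _ in range(max_iter):
        current = total_score(S, T, n)
        in_set = np.zeros(n_total, dtype=bool)
        in_set[site_idx] = True
        phi_up = phi(counts + 1.5) - phi(counts + 0.5)    # cell gain on add
        with np.errstate(invalid="ignore"):
            # cells at count 0 yield NaN but are never gathered by a remove
            phi_down = phi(counts + 0.5) - phi(counts - 0.5)
        best_gain, best_move = 0.0, None
        out_idx = np.flatnonzero(~in_set)
        if len(out_idx):
            dS = phi_up[words[out_idx], cols].sum(axis=1)
            add_scores = total_score(S + dS, T + word_bg[out_idx], n + 1)
            j = int(np.argmax(add_scores))
            if add_scores[j] - current > best_gain + 1e-12:
                best_gain, best_move = add_scores[j] - current, ("add", int(out_idx[j]))
        if n > 2:
            site_arr = np.asarray(site_idx)
            dS = phi_down[words[site_arr], cols].sum(axis=1)
            rem_scores = total_score(S - dS, T - word_bg[site_arr], n - 1)
            j = int(np.argmax(rem_scores))
            if rem_scores[j] - current > best_gain + 1e-12:
                best_gain, best_move = rem_scores[j] - current, ("remove", j)
        if best_move is None:
            break
        kind, j = best_move
        if kind == "add":
            S += phi_up[words[j], cols].sum()
            T += word_bg[j]
            counts[words[j], cols] += 1.0
            n += 1
            site_idx.append(j)
        else:
            idx = site_idx[j]
            S -= phi_down[words[idx], cols].sum()
            T -= word_bg[idx]
            counts[words[idx], cols] -= 1.0
            n -= 1
            site_idx.pop(j)
    return site_idx


def find_motifs(
    foreground: Mapping[str, str],
    background: Mapping[str, str] | None = None,
    w: int = 8,
    top_t: int = 5,
    match_threshold: int | None = None,
    max_candidates: int = 30,
    max_iter: int = 100,
) -> list[MotifModel]:
    """Discover over-represented width-w motifs in ranked foreground sequences.

    Sequences are taken in mapping order (best-ranked first); every w-mer of
    the first ``top_t`` sequences (both strands) seeds a candidate from all
    foreground w-mers matching it at >= ``match_threshold`` (default w - 2)
    positions.  The ``max_candidates`` best-scoring candidates are refined
    greedily and returned deduplicated by consensus, best first.
    """
    if match_threshold is None:
        match_threshold = w - 2
    names = list(foreground)
    if any(len(foreground[n]) < w for n in names):
        raise ValueError("motif width exceeds the shortest sequence")
    top_t = min(top_t, len(names))
    bg = (
        background_frequencies(background)
        if background is not None
        else np.full(4, 0.25)
    )
    W, onehot, sites = _all_wmers(foreground, w)
    top_names = set(names[:top_t])
    seed_rows = np.flatnonzero(np.array([s[0] in top_names for s in sites]))
    seeds = np.unique(W[seed_rows], axis=0)
    candidates: dict[tuple[int, ...], list[int]] = {}
    for seed in seeds:
        match = (W == seed).sum(axis=1) >= match_threshold
        idx = np.flatnonzero(match)
        if len(idx) >= 2:
            candidates.setdefault(tuple(idx.tolist()), idx.tolist())
    scored = []
    for idx in candidates.values():
        counts = onehot[idx].sum(axis=0)
        s = float(_score_from_counts(counts, len(idx), bg))
        consensus = decode(np.argmax(counts, axis=0))
        scored.append((-s, consensus, idx))
    scored.sort(key=lambda t: (t[0], t[1]))
    results: dict[str, MotifModel] = {}
    for _, _, idx in scored[:max_candidates]:
        refined = _refine(idx, onehot, bg, max_iter=max_iter, words=W)
        counts = onehot[refined].sum(axis=0)
        model = MotifModel(
            width=w,
            counts=counts,
            sites=[sites[i] for i in sorted(refined)],
            score=float(_score_from_counts(counts, len(refined), bg)),
        )
        prev = results.get(model.consensus)
        if prev is None or model.score > prev.score:
            results[model.consensus] = model
    return sorted(results.values(), key=lambda m: (-m.score, m.consensus))


def _iupac_match_positions(seq: str, pattern: str) -> set[int]:
    allowed = []
    for ch in pattern:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r} in pattern")
        allowed.append(set(IUPAC[ch]))
    w = len(pattern)
    return {
        i
        for i in range(len(seq) - w + 1)
        if all(seq[i + j] in allowed[j] for j in range(w))
    }


def scan_iupac(sequences: Mapping[str, str], pattern: str) -> dict[str, int]:
    """Count occurrences of an IUPAC pattern per sequence, both strands.

    Overlapping occurrences count; a position matched by both the pattern
    and its reverse complement (strand-symmetric patterns) counts once.
    """
    rc = revcomp(pattern)
    out = {}
    for name, seq in sequences.items():
        hits = _iupac_match_positions(seq, pattern) | _iupac_match_positions(seq, rc)
        out[name] = len(hits)
    return out
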