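"""Independent brute-force oracles used by the test suite.

Everything here recomputes pipeline quantities from first principles by
exhaustive scanning, deliberately sharing no code with the package's
seeded-index implementation.
"""

from __future__ import annotations

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _codes(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq], dtype=np.uint8)


def naive_hits(read: str, references: dict[str, str], v: int):
    """Full double-loop Hamming scan, both orientations, every reference.

    Returns a sorted list of (target, position, strand, mismatches).
    N mismatches everything, including N.
    """
    out = []
    for name, ref in references.items():
        ref_c = _codes(ref)
        for strand, oriented in (("+", read), ("-", revcomp(read))):
            rd = _codes(oriented)
            L = rd.size
            if L > ref_c.size:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref_c, L)
            mism = ((windows != rd) | (windows == 4) | (rd == 4)).sum(axis=1)
            for pos in np.flatnonzero(mism <= v):
                out.append((name, int(pos), strand, int(mism[pos])))
    out.sort()
    return out


def _onehot_windows(ref: str, L: int) -> np.ndarray:
    """(positions, L*5) float32 one-hot windows; N rows are zero."""
    codes = _codes(ref)
    oh = np.zeros((codes.size, 5), dtype=np.float32)
    valid = codes < 4
    oh[np.arange(codes.size)[valid], codes[valid]] = 1.0
    win = np.lib.stride_tricks.sliding_window_view(oh, (L, 5))
    return np.ascontiguousarray(win.reshape(codes.size - L + 1, L * 5))


def matmul_scan_hits(
    reads: list[str], references: dict[str, str], v: int, batch: int = 256
):
    """Exhaustive scan of every read against every window of every
    reference via one-hot match counting (a naive full scan in matrix
    form).  Returns per-read sorted hit lists like :func:`naive_hits`.
    """
    n = len(reads)
    L = len(reads[0])
    assert all(len(r) == L for r in reads)
    hits: list[list] = [[] for _ in range(n)]
    # 2n columns: forward then reverse-complement orientation per read
    oriented = reads + [revcomp(r) for r in reads]
    R = np.zeros((2 * n, L * 5), dtype=np.float32)
    for i, seq in enumerate(oriented):
        codes = _codes(seq)
        valid = codes < 4
        flat = np.arange(L) * 5 + codes
        R[i, flat[valid]] = 1.0
    for name, ref in references.items():
        if len(ref) < L:
            continue
        W = _onehot_windows(ref, L)
        for lo in range(0, 2 * n, batch):
            block = R[lo : lo + batch]
            matches = W @ block.T  # (positions, block)
            mism = L - matches
            pos_idx, col_idx = np.nonzero(mism <= v + 0.5)
            for p, c in zip(pos_idx, col_idx):
                col = lo + c
                read_i = col % n
                strand = "+" if col < n else "-"
                hits[read_i].append(
                    (name, int(p), strand, int(round(mism[p, c])))
                )
    for h in hits:
        h.sort()
    return hits


def oracle_classify(hits, best_stratum: bool = True) -> tuple[str, list]:
    """(class, kept hits) from a hit list, by the best-stratum rule."""
    kept = list(hits)
    if best_stratum and kept:
        best = min(h[3] for h in kept)
        kept = [h for h in kept if h[3] == best]
    if not kept:
        return "unmapped", []
    return ("unique" if len(kept) == 1 else "multi"), kept


def oracle_unique_subfamily(contig, pos, read_len, instances):
    """Linear scan over all instances: any-overlap assignment with the
    larger-overlap-then-lexicographic tie-break.  `instances` is a list
    of (contig, start, end, subfamily, instance_id)."""
    start, end = pos, pos + read_len
    best = None
    for c, s, e, subfam, iid in instances:
        if c != contig:
            continue
        ov = min(e, end) - max(s, start)
        if ov <= 0:
            continue
        key = (-ov, subfam, iid)
        if best is None or key < best[0]:
            best = (key, subfam, iid)
    if best is None:
        return None
    return best[1], best[2]


def oracle_fractional_counts(
    reads: dict[str, str],
    genome: dict[str, str],
    instances: list,
    pseudogenomes: dict[str, str],
    v: int,
    use_matmul: bool = True,
):
    """Full two-pass pipeline by exhaustive scanning.

    Returns (per-subfamily fractional counts, ledger dict).  `instances`
    rows are (contig, start, end, subfamily, instance_id).
    """
    names = list(reads)
    seqs = [reads[k] for k in names]
    if use_matmul:
        genome_hits = matmul_scan_hits(seqs, genome, v)
    else:
        genome_hits = [naive_hits(s, genome, v) for s in seqs]
    counts: dict[str, float] = {}
    ledger = {
        "unique_overlap": 0,
        "unique_non_overlap": 0,
        "multi_assigned": 0,
        "multi_unassigned": 0,
        "unmapped": 0,
    }
    multi_idx = []
    for i, name in enumerate(names):
        cls, kept = oracle_classify(genome_hits[i])
        if cls == "unmapped":
            ledger["unmapped"] += 1
        elif cls == "unique":
            target, pos, strand, _ = kept[0]
            res = oracle_unique_subfamily(target, pos, len(seqs[i]), instances)
            if res is None:
                ledger["unique_non_overlap"] += 1
            else:
                ledger["unique_overlap"] += 1
                counts[res[0]] = counts.get(res[0], 0.0) + 1.0
        else:
            multi_idx.append(i)
    if multi_idx:
        multi_seqs = [seqs[i] for i in multi_idx]
        if use_matmul:
            pg_hits = matmul_scan_hits(multi_seqs, pseudogenomes, v)
        else:
            pg_hits = [naive_hits(s, pseudogenomes, v) for s in multi_seqs]
        for h in pg_hits:
            subfams = {t[0] for t in h}
            if not subfams:
                ledger["multi_unassigned"] += 1
                continue
            ledger["multi_assigned"] += 1
            w = 1.0 / len(subfams)
            for s in subfams:
                counts[s] = counts.get(s, 0.0) + w
    return counts, ledger


def poisson_lrt_stat(y_a, y_b, off_a, off_b):
    """Closed-form Poisson deviance difference for a two-group contrast
    with per-sample exposure offsets (log scale)."""
    y_a, y_b = np.asarray(y_a, float), np.asarray(y_b, float)
    e_a, e_b = np.exp(off_a), np.exp(off_b)

    def loglik(y, mu):
        from scipy.special import gammaln, xlogy

        return float(np.sum(xlogy(y, mu) - mu - gammaln(y + 1)))

    mu_a = e_a * y_a.sum() / e_a.sum() if y_a.sum() > 0 else np.zeros_like(e_a)
    mu_b = e_b * y_b.sum() / e_b.sum() if y_b.sum() > 0 else np.zeros_like(e_b)
    pooled = (y_a.sum() + y_b.sum()) / (e_a.sum() + e_b.sum())
    ll_full = loglik(y_a, np.maximum(mu_a, 1e-300)) + loglik(
        y_b, np.maximum(mu_b, 1e-300)
    )
    ll_null = loglik(y_a, np.maximum(e_a * pooled, 1e-300)) + loglik(
        y_b, np.maximum(e_b * pooled, 1e-300)
    )
    return 2.0 * (ll_full - ll_null)
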