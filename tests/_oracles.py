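"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops, deliberately sharing no
code with the package, so agreement is meaningful.
"""

from __future__ import annotations

import pandas as pd


def overlap_bruteforce(counts: pd.DataFrame, members_a, members_b) -> float:
    pooled = list(dict.fromkeys(list(members_a) + list(members_b)))
    genera = list(counts.columns)
    n_total = 0
    for s in pooled:
        for g in genera:
            n_total += counts.loc[s, g]
    detected_a = {g for g in genera if any(counts.loc[s, g] > 0 for s in members_a)}
    detected_b = {g for g in genera if any(counts.loc[s, g] > 0 for s in members_b)}
    acc = 0.0
    for g in detected_a & detected_b:
        total = sum(counts.loc[s, g] for s in pooled)
        frac = sum(1 for s in pooled if counts.loc[s, g] > 0) / len(pooled)
        acc += total * frac
    return 100.0 * acc / n_total


def chao1_bruteforce(row) -> float:
    row = list(row)
    s_obs = sum(1 for v in row if v > 0)
    f1 = sum(1 for v in row if v == 1)
    f2 = sum(1 for v in row if v == 2)
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def inverse_simpson_bruteforce(row) -> float:
    total = sum(row)
    return 1.0 / sum((v / total) ** 2 for v in row)


def bray_curtis_bruteforce(x, y) -> float:
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def best_ungapped_identity(a: str, b: str, min_len: int):
    """(best identity, alignment length) over all ungapped offsets; char loops."""
    best_ident, best_len = 0.0, 0
    for off in range(-(len(b) - min_len), len(a) - min_len + 1):
        a0, b0 = max(0, off), max(0, -off)
        length = min(len(a) - a0, len(b) - b0)
        if length < min_len:
            continue
        matches = sum(
            1 for i in range(length) if a[a0 + i] == b[b0 + i]
        )
        ident = matches / length
        if ident > best_ident or (ident == best_ident and length > best_len):
            best_ident, best_len = ident, length
    return best_ident, best_len


def match_contaminant_bruteforce(
    sequence: str,
    control_sequences,
    min_len: int = 250,
    threshold: float = 0.99,
    check_revcomp: bool = True,
) -> bool:
    """All-pairs, no prefilter: matched iff any control aligns above threshold."""
    for ctl in control_sequences:
        targets = [ctl, _revcomp(ctl)] if check_revcomp else [ctl]
        for t in targets:
            ident, length = best_ungapped_identity(sequence, t, min_len)
            if length >= min_len and ident >= threshold:
                return True
    return False
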