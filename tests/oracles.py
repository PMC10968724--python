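"""Independent brute-force oracles used to cross-check the package.

These deliberately share no code with the implementation: quadratic
dynamic programming and exhaustive enumeration only.
"""

from __future__ import annotations

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def revcomp_naive(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def longest_inverted_repeat_naive(seq: str) -> int:
    """Length of the longest pair of exact, non-overlapping inverted repeats.

    Quadratic DP: a common substring of ``seq`` and its reverse complement
    of length k at (i, j) corresponds to arms ``[i-k, i)`` and
    ``[n-j, n-j+k)``; the arms must not overlap.
    """
    n = len(seq)
    rc = revcomp_naive(seq)
    best = 0
    prev = [0] * (n + 1)
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if seq[i - 1] == rc[j - 1]:
                k = prev[j - 1] + 1
                cur[j] = k
                b_start = n - j
                if i <= b_start:
                    valid = k
                else:
                    valid = min(k, (i - b_start) // 2)
                if valid > best:
                    best = valid
        prev = cur
    return best


def nw_unit_cost(a: str, b: str) -> int:
    """Global alignment cost (match 0, mismatch 1, gap 1), full DP."""
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j - 1] + (ai != b[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[lb]


def specimen_variant_columns_naive(rows: list[tuple[str, str]]) -> list[tuple[int, str, str]]:
    """Per-column (column, specimen, kind) classification, no run merging."""
    ids = [r[0] for r in rows]
    seqs = [r[1] for r in rows]
    out = []
    for col in range(len(seqs[0])):
        column = [s[col] for s in seqs]
        for i in range(len(rows)):
            others = column[:i] + column[i + 1 :]
            if len(set(others)) == 1 and others[0] != column[i]:
                minor, major = column[i], others[0]
                if minor == "-":
                    kind = "deletion"
                elif major == "-":
                    kind = "insertion"
                else:
                    kind = "substitution"
                out.append((col, ids[i], kind))
                break
    return out


def iupac_expansions(site: str) -> list[str]:
    """All literal ACGT words matching an IUPAC site."""
    table = {
        "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
        "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
        "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    words = [""]
    for ch in site:
        words = [w + x for w in words for x in table[ch]]
    return words
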