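"""Independent quadratic dynamic-programming oracle for local alignment.

A plain Gotoh affine-gap Smith–Waterman in pure Python: score matrices
filled explicitly, traceback by recorded moves with a fixed precedence
(diagonal, then gap-in-query, then gap-in-ref). Deliberately naive and
separate from the package's alignment path so it can vouch for it.

Gap convention matches the package scoring: the first residue of a gap
costs ``gap_open``; each further residue ``gap_extend``.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

NEG = float("-inf")


def gotoh_local(query: str, ref: str, matrix_name: str = "BLOSUM62",
                gap_open: float = 11.0, gap_extend: float = 1.0):
    """Optimal local alignment by explicit DP.

    Returns (score, identity, query_coverage, ref_coverage) where identity
    and coverages are computed from one optimal traceback: identical
    aligned positions over aligned columns (substitutions plus internal
    gaps), and aligned residues over full sequence lengths.
    """
    sub = substitution_matrices.load(matrix_name)
    n, m = len(query), len(ref)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (consumes query)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consumes ref)
    best, best_pos = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_extend)
            diag = H[i - 1][j - 1] + sub[query[i - 1], ref[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_pos = H[i][j], (i, j)
    if best == 0.0:
        return 0.0, 0.0, 0.0, 0.0

    # traceback one optimal path
    i, j = best_pos
    identities = columns = q_res = r_res = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0.0:
                break
            diag = H[i - 1][j - 1] + sub[query[i - 1], ref[j - 1]]
            if H[i][j] == diag:
                identities += query[i - 1] == ref[j - 1]
                columns += 1
                q_res += 1
                r_res += 1
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            q_res += 1
            if E[i][j] == H[i - 1][j] - gap_open:
                state = "H"
            i -= 1
        else:  # F
            columns += 1
            r_res += 1
            if F[i][j] == H[i][j - 1] - gap_open:
                state = "H"
            j -= 1
    return (
        best,
        identities / columns if columns else 0.0,
        q_res / len(query),
        r_res / len(ref),
    )
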