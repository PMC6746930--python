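"""Independent brute-force oracle for the subgenome divergence index.

Pure-Python, loop-by-loop transcription of the refined windowed statistic:
no numpy vectorization, no shared code with the production implementation.
Returns None where the statistic is undefined (no informative window).
"""


def naive_pindex(
    rates_by_chrom,
    tau=0.05,
    pair_set=None,
    pair_norm="pairs",
    weight_scheme="informative",
    denominator_scheme="informative_pairs",
):
    per_chrom = []
    for chrom in rates_by_chrom:
        A = rates_by_chrom[chrom]
        S = len(A)
        N = len(A[0])
        pairs = list(pair_set) if pair_set else [
            (k, j) for k in range(S) for j in range(k + 1, S)
        ]
        divisor = len(pairs) if pair_norm == "pairs" else S
        deltas = []
        for i in range(N):
            total = 0.0
            for (k, j) in pairs:
                a, b = A[k][i], A[j][i]
                if a + b > 0:
                    total += abs(a - b) / (0.5 * (a + b))
            deltas.append(1 if total / divisor >= tau else 0)
        n_inf = sum(deltas)
        if n_inf == 0:
            continue
        numerator = 0.0
        for (k, j) in pairs:
            for i in range(N):
                a, b = A[k][i], A[j][i]
                sign = 0 if a == b else (1 if a > b else -1)
                numerator += sign * deltas[i]
        if denominator_scheme == "informative_pairs":
            denom = n_inf * len(pairs)
        else:
            denom = N * len(pairs) - (N - n_inf)
        per_chrom.append((N, n_inf, abs(numerator) / denom))
    if not per_chrom:
        return None
    weights = [
        (n_inf if weight_scheme == "informative" else N)
        for (N, n_inf, _term) in per_chrom
    ]
    wsum = sum(weights)
    return sum(
        (w / wsum) * term for w, (_N, _n, term) in zip(weights, per_chrom)
    )
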