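"""The polyploidy index (P-index): a fractionation-bias statistic.

After a whole-genome duplication, duplicated genes are gradually lost
(fractionation). In an autopolyploid the initially identical subgenomes
lose genes at similar rates in any given region; in an allopolyploid one
diverged subgenome is typically dominant and the loss is one-sided. The
P-index quantifies how consistently one subgenome out-retains the other
along the genome:

    P = sum_c W_c * | sum_i sign(A_i - B_i) * delta_i | / (N_c - delta(N_c))

where A_i, B_i are windowed retention rates against an outgroup reference,
delta_i flags windows whose relative retention difference exceeds tau, and
N_c - delta(N_c) is the number of informative windows on chromosome c.
Chromosome weights W_c are proportional to informative-window counts
(``weight_scheme='informative'``) or raw window counts (``'raw'``) and sum
to 1, so P lies in [0, 1]: near 0 under balanced loss (auto-like), near 1
under consistently one-sided loss (allo-like).

For S > 2 subgenomes the signed sum runs over subgenome pairs; dividing by
(informative windows x number of pairs) keeps the statistic in [0, 1] and
reduces exactly to the two-track form at S = 2. The literal published
denominator N x C(S,2) - delta(N) is available as
``denominator_scheme='printed'``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .retention import RetentionProfile, WindowFlags, compute_flags, profile_from_masks

__all__ = [
    "PIndexModel",
    "PIndexResults",
    "SelfRefResults",
    "HomoeologTriple",
    "SubgenomeDistanceMatrix",
    "ClassificationResult",
    "pindex_pair",
    "pindex_multi",
    "pindex_selfref",
    "pindex_recursive",
    "pairwise_matrix",
    "classify",
    "classify_event_table",
]


@dataclass
class PIndexResults:
    """Fitted P-index with per-chromosome decomposition.

    ``per_chromosome`` has one row per included chromosome: window count N,
    informative count n, term T in [0, 1] and normalized weight W (weights
    sum to 1 when ``status == 'ok'``). ``status`` is ``'undefined'`` when no
    chromosome carries an informative window; the index is then reported as
    0 but flagged.
    """

    pindex: float
    status: str
    mode: str
    S: int
    per_chromosome: pd.DataFrame
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pindex": self.pindex,
            "status": self.status,
            "mode": self.mode,
            "S": self.S,
            "per_chromosome": self.per_chromosome.to_dict(orient="list"),
            "params": self.params,
        }

    def summary(self) -> str:
        lines = [
            "P-index results",
            "=" * 46,
            f"mode:       {self.mode}",
            f"subgenomes: {self.S}",
            f"status:     {self.status}",
            f"P-index:    {self.pindex:.4f}",
        ]
        for key, value in sorted(self.params.items()):
            lines.append(f"{key}: {value}")
        lines.append("-" * 46)
        if len(self.per_chromosome):
            lines.append(
                self.per_chromosome.to_string(
                    index=False, float_format=lambda v: f"{v:.4f}"
                )
            )
        else:
            lines.append("(no informative chromosome)")
        return "\n".join(lines)


_CHROM_COLUMNS = ["chromosome", "N", "n_informative", "term", "weight"]


class PIndexModel:
    """P-index model over a windowed retention profile.

    Parameters
    ----------
    profile : RetentionProfile
        Windowed retention rates for S subgenome tracks.
    tau : float
        Informative-window threshold on the relative retention difference.
    pair_set : iterable of (k, j) or None
        Subgenome pairs compared; default all k < j.
    pair_norm : {'pairs', 'S'}
        Divisor of the aggregated window difference for S > 2.
    weight_scheme : {'informative', 'raw'}
        Chromosome weights proportional to informative or raw window counts.
    denominator_scheme : {'informative_pairs', 'printed'}
        Per-chromosome term denominator for S > 2 (see module docstring).
    """

    def __init__(
        self,
        profile: RetentionProfile,
        tau: float = 0.05,
        pair_set=None,
        pair_norm: str = "pairs",
        weight_scheme: str = "informative",
        denominator_scheme: str = "informative_pairs",
    ):
        if weight_scheme not in ("informative", "raw"):
            raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
        if denominator_scheme not in ("informative_pairs", "printed"):
            raise ValueError(f"unknown denominator_scheme {denominator_scheme!r}")
        self.profile = profile
        self.tau = tau
        S = profile.S
        if pair_set is None:
            pair_set = tuple(itertools.combinations(range(S), 2))
        self.pair_set = tuple(tuple(p) for p in pair_set)
        if not self.pair_set:
            raise ValueError("pair_set is empty")
        self.pair_norm = pair_norm
        self.weight_scheme = weight_scheme
        self.denominator_scheme = denominator_scheme

    @classmethod
    def from_assignment(
        cls, assignment, M: int = 100, min_last_window: float = 0.5, **kwargs
    ) -> "PIndexModel":
        """Build the model from a subgenome assignment (windows it first)."""
        from .retention import compute_retention

        return cls(compute_retention(assignment, M, min_last_window), **kwargs)

    @classmethod
    def from_masks(
        cls, masks: dict, M: int = 100, min_last_window: float = 0.5, **kwargs
    ) -> "PIndexModel":
        """Build the model from boolean retention masks (simulation path)."""
        return cls(profile_from_masks(masks, M, min_last_window), **kwargs)

    def fit(self, flags: WindowFlags | None = None) -> PIndexResults:
        """Compute the P-index; returns a :class:`PIndexResults`."""
        profile = self.profile
        if flags is None:
            flags = compute_flags(
                profile, tau=self.tau, pair_set=self.pair_set, pair_norm=self.pair_norm
            )
        n_pairs = len(self.pair_set)
        rows = []
        for chrom, A in profile.rates.items():
            delta = flags.delta[chrom]
            N_c = len(delta)
            n_c = int(delta.sum())
            if n_c == 0:
                continue
            signed = 0.0
            for k, j in self.pair_set:
                signed += float(np.sum(np.sign(A[k] - A[j]) * delta))
            if self.denominator_scheme == "informative_pairs":
                denom = n_c * n_pairs
            else:  # literal published form
                denom = N_c * n_pairs - (N_c - n_c)
            T_c = abs(signed) / denom
            rows.append((chrom, N_c, n_c, T_c))
        mode = "pair" if profile.S == 2 and n_pairs == 1 else "multi"
        params = {
            "M": profile.M,
            "tau": flags.tau,
            "pair_set": list(map(list, self.pair_set)),
            "pair_norm": self.pair_norm,
            "weight_scheme": self.weight_scheme,
            "denominator_scheme": self.denominator_scheme,
        }
        if not rows:
            return PIndexResults(
                pindex=0.0,
                status="undefined",
                mode=mode,
                S=profile.S,
                per_chromosome=pd.DataFrame(columns=_CHROM_COLUMNS),
                params=params,
            )
        df = pd.DataFrame(rows, columns=["chromosome", "N", "n_informative", "term"])
        if self.weight_scheme == "informative":
            w = df["n_informative"].to_numpy(dtype=float)
        else:
            w = df["N"].to_numpy(dtype=float)
        df["weight"] = w / w.sum()
        pindex = float((df["weight"] * df["term"]).sum())
        return PIndexResults(
            pindex=pindex,
            status="ok",
            mode=mode,
            S=profile.S,
            per_chromosome=df,
            params=params,
        )


# ---------------------------------------------------------------------------
# convenience fit functions

def pindex_pair(
    profile: RetentionProfile,
    flags: WindowFlags | None = None,
    tau: float = 0.05,
    weight_scheme: str = "informative",
) -> PIndexResults:
    """Two-subgenome P-index (refined formula; raw-weight variant optional)."""
    if profile.S != 2:
        raise ValueError(
            f"profile has {profile.S} subgenomes; use pindex_multi for S != 2"
        )
    model = PIndexModel(profile, tau=tau, weight_scheme=weight_scheme)
    return model.fit(flags)


def pindex_multi(
    profile: RetentionProfile,
    flags: WindowFlags | None = None,
    tau: float = 0.05,
    pair_set=None,
    pair_norm: str = "pairs",
    weight_scheme: str = "informative",
    denominator_scheme: str = "informative_pairs",
) -> PIndexResults:
    """S-subgenome P-index over a set of compared subgenome pairs."""
    model = PIndexModel(
        profile,
        tau=tau,
        pair_set=pair_set,
        pair_norm=pair_norm,
        weight_scheme=weight_scheme,
        denominator_scheme=denominator_scheme,
    )
    return model.fit(flags)


# ---------------------------------------------------------------------------
# self-reference mode (no outgroup; e.g. a conserved paleohexaploid genome)

@dataclass
class HomoeologTriple:
    """Three homoeologous regions of one genome over ancestral gene slots.

    ``presence`` is a (3, n) boolean matrix: presence[r, i] says whether
    copy r retains the gene at ancestral slot i. One copy serves as the
    internal reference; slots the reference itself lost are skipped, which
    amounts to randomly subsampling the loss record of the other two copies.
    """

    presence: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.ndim != 2 or self.presence.shape[0] != 3:
            raise ValueError("presence must be a (3, n) boolean matrix")


@dataclass
class SelfRefResults:
    """Self-reference P-index for each rotation of the internal reference."""

    per_reference: list[PIndexResults]
    mean_pindex: float

    def summary(self) -> str:
        lines = ["Self-reference P-index (rotations)"]
        for r, res in enumerate(self.per_reference):
            lines.append(f"  reference copy {r}: {res.pindex:.4f} ({res.status})")
        lines.append(f"  mean: {self.mean_pindex:.4f}")
        return "\n".join(lines)


def _selfref_profile(
    triples: list[HomoeologTriple], reference_index: int, M: int, min_last_window: float
) -> RetentionProfile:
    masks = {}
    others = [r for r in range(3) if r != reference_index]
    for t, triple in enumerate(triples):
        keep = triple.presence[reference_index]
        if not keep.any():
            continue
        masks[triple.label or f"triple{t}"] = triple.presence[others][:, keep]
    if not masks:
        raise ValueError("internal reference retains no genes in any triple")
    return profile_from_masks(masks, M=M, min_last_window=min_last_window)


def pindex_selfref(
    triples,
    M: int = 100,
    tau: float = 0.05,
    reference_index: int = 0,
    rotate: bool = False,
    min_last_window: float = 0.5,
):
    """P-index of a polyploidy using one homoeologous copy as the reference.

    Each triple designates one region as internal reference; windows are
    built over that copy's *retained* genes only, and the other two copies
    yield a two-track retention profile. With ``rotate=True`` all three
    reference choices are evaluated and returned with their mean.
    """
    triples = list(triples)
    for t in triples:
        if not isinstance(t, HomoeologTriple):
            raise TypeError("triples must be HomoeologTriple instances")
    if rotate:
        results = [
            pindex_pair(
                _selfref_profile(triples, r, M, min_last_window), tau=tau
            )
            for r in range(3)
        ]
        for r, res in enumerate(results):
            res.mode = "selfref"
            res.params["reference_index"] = r
        return SelfRefResults(
            per_reference=results,
            mean_pindex=float(np.mean([r.pindex for r in results])),
        )
    res = pindex_pair(_selfref_profile(triples, reference_index, M, min_last_window), tau=tau)
    res.mode = "selfref"
    res.params["reference_index"] = reference_index
    return res


# ---------------------------------------------------------------------------
# recursive events (two rounds of polyploidy in one genome)

def pindex_recursive(
    profile: RetentionProfile,
    pairing: tuple[tuple[int, int], tuple[int, int]] = ((0, 1), (2, 3)),
    tau: float = 0.05,
    weight_scheme: str = "informative",
) -> tuple[PIndexResults, PIndexResults]:
    """P-indices of the younger and older of two stacked polyploidies.

    ``profile`` holds four tracks; ``pairing`` partitions them into the two
    sibling pairs produced by the younger event (alpha), whose parent copies
    descend from the older event (beta). Returns ``(alpha, beta)``:

    * alpha — within each sibling pair a two-track term is computed per
      chromosome; the two terms are pooled by informative-window-weighted
      mean before chromosome weighting.
    * beta — the multi-subgenome statistic restricted to the four
      cross-pair comparisons.
    """
    if profile.S != 4:
        raise ValueError(f"recursive mode needs a 4-track profile, got S={profile.S}")
    flat = sorted(pairing[0]) + sorted(pairing[1])
    if sorted(flat) != [0, 1, 2, 3] or len(pairing) != 2:
        raise ValueError(f"pairing {pairing} is not a partition of the 4 tracks")

    # alpha: pooled within-pair pairwise computation
    sub_results = []
    for pair in pairing:
        sub = profile.subset_tracks(tuple(sorted(pair)))
        sub_flags = compute_flags(sub, tau=tau)
        sub_results.append((sub, sub_flags))
    rows = []
    for chrom in profile.chromosomes:
        N_c = profile.n_windows(chrom)
        pooled_num = 0.0
        pooled_n = 0
        for sub, sub_flags in sub_results:
            delta = sub_flags.delta[chrom]
            n_c = int(delta.sum())
            if n_c == 0:
                continue
            A = sub.rates[chrom]
            T = abs(float(np.sum(np.sign(A[0] - A[1]) * delta))) / n_c
            pooled_num += n_c * T
            pooled_n += n_c
        if pooled_n == 0:
            continue
        rows.append((chrom, N_c, pooled_n, pooled_num / pooled_n))
    params = {"M": profile.M, "tau": tau, "pairing": [list(p) for p in pairing],
              "weight_scheme": weight_scheme}
    if rows:
        df = pd.DataFrame(rows, columns=["chromosome", "N", "n_informative", "term"])
        w = (
            df["n_informative"] if weight_scheme == "informative" else df["N"]
        ).to_numpy(dtype=float)
        df["weight"] = w / w.sum()
        alpha = PIndexResults(
            pindex=float((df["weight"] * df["term"]).sum()),
            status="ok",
            mode="recursive_alpha",
            S=4,
            per_chromosome=df,
            params=params,
        )
    else:
        alpha = PIndexResults(
            pindex=0.0,
            status="undefined",
            mode="recursive_alpha",
            S=4,
            per_chromosome=pd.DataFrame(columns=_CHROM_COLUMNS),
            params=params,
        )

    cross = tuple(
        (k, j) if k < j else (j, k) for k in pairing[0] for j in pairing[1]
    )
    beta = pindex_multi(profile, tau=tau, pair_set=cross, weight_scheme=weight_scheme)
    beta.mode = "recursive_beta"
    return alpha, beta


# ---------------------------------------------------------------------------
# pairwise distance matrix over subgenomes

@dataclass
class SubgenomeDistanceMatrix:
    """Pairwise P-indices between subgenome tracks, with grouping.

    The matrix is symmetric with zero diagonal. ``groups`` is the partition
    (average-linkage agglomeration, cut at the number of groups maximizing
    mean between-group minus mean within-group distance over 2..S-1 groups).
    ``integrated_within[g]`` is the mean pairwise entry inside group g (nan
    for singletons); ``integrated_between`` the mean entry across groups.
    """

    matrix: np.ndarray
    groups: list[list[int]]
    integrated_within: list[float]
    integrated_between: float

    def to_frame(self) -> pd.DataFrame:
        S = self.matrix.shape[0]
        labels = [f"sub{k + 1}" for k in range(S)]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


def pairwise_matrix(
    profile: RetentionProfile, tau: float = 0.05
) -> SubgenomeDistanceMatrix:
    """All-pairs P-index between S >= 3 subgenome tracks, with grouping."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    S = profile.S
    if S < 3:
        raise ValueError(f"pairwise matrix needs S >= 3, got S={S}")
    mat = np.zeros((S, S))
    for k, j in itertools.combinations(range(S), 2):
        res = pindex_pair(profile.subset_tracks((k, j)), tau=tau)
        mat[k, j] = mat[j, k] = res.pindex

    condensed = squareform(mat, checks=False)
    Z = linkage(condensed, method="average")
    best = None
    for g in range(2, S):
        membership = fcluster(Z, t=g, criterion="maxclust")
        within, between = [], []
        for k, j in itertools.combinations(range(S), 2):
            (within if membership[k] == membership[j] else between).append(mat[k, j])
        if not between:
            continue
        score = float(np.mean(between)) - (float(np.mean(within)) if within else 0.0)
        if best is None or score > best[0]:
            best = (score, membership)
    membership = best[1]
    group_ids = sorted(set(membership), key=lambda gid: min(
        k for k in range(S) if membership[k] == gid
    ))
    groups = [[k for k in range(S) if membership[k] == gid] for gid in group_ids]
    within_means = []
    for members in groups:
        entries = [mat[k, j] for k, j in itertools.combinations(members, 2)]
        within_means.append(float(np.mean(entries)) if entries else float("nan"))
    between_entries = [
        mat[k, j]
        for k, j in itertools.combinations(range(S), 2)
        if membership[k] != membership[j]
    ]
    return SubgenomeDistanceMatrix(
        matrix=mat,
        groups=groups,
        integrated_within=within_means,
        integrated_between=float(np.mean(between_entries)),
    )


# ---------------------------------------------------------------------------
# classification

@dataclass
class ClassificationResult:
    """Allo/auto verdict for one polyploidy event.

    The event-level index is the mean over the event's per-reference values;
    the verdict is allopolyploid iff it strictly exceeds the threshold
    (default 0.3), so a boundary value classifies as autopolyploid.
    """

    event_label: str
    pindex_values: list[float]
    event_pindex: float
    verdict: str
    threshold: float = 0.3


def classify(
    values, threshold: float = 0.3, label: str = ""
) -> ClassificationResult:
    """Classify an event from one or more P-index values (mean, strict >)."""
    values = [float(v) for v in values]
    if not values:
        raise ValueError("no values to classify")
    for v in values:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"P-index value {v} outside [0, 1]")
    mean = float(np.mean(values))
    return ClassificationResult(
        event_label=label,
        pindex_values=values,
        event_pindex=mean,
        verdict="allo" if mean > threshold else "auto",
        threshold=threshold,
    )


def classify_event_table(fixture, threshold: float = 0.3) -> pd.DataFrame:
    """Classify every event of an event-table fixture.

    Returns one row per event with the mean index and verdict; the frame
    carries ``percent_allo`` (over all events) in ``df.attrs``.
    """
    df = fixture.events
    rows = []
    for event_number, sub in df.groupby("event_number", sort=True):
        res = classify(
            sub["pindex_value"].tolist(),
            threshold=threshold,
            label=str(sub["event_name"].iloc[0]),
        )
        rows.append(
            (
                event_number,
                res.event_label,
                len(res.pindex_values),
                res.event_pindex,
                res.verdict,
                sub["printed_nature"].iloc[0],
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "event_number",
            "event_name",
            "n_values",
            "event_pindex",
            "verdict",
            "printed_nature",
        ],
    )
    out.attrs["percent_allo"] = 100.0 * (out["verdict"] == "allo").mean()
    out.attrs["threshold"] = threshold
    return out
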