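"""Simulation of post-polyploidy gene loss in geometric-length runs.

Fractionation removes duplicated genes in contiguous runs whose lengths are
well described by a geometric distribution. The simulator repeatedly picks
a uniformly random still-retained gene, draws a run length L ~
Geometric(p) (support 1, 2, ...; mean 1/p), and deletes the next L
still-retained genes in rank order, until the retained fraction falls to
the per-subgenome target. Balanced scenarios give every subgenome the same
retention target (the autopolyploid null); unbalanced scenarios give the
subgenomes distinct targets (allopolyploid-like biased fractionation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PIndexModel

__all__ = [
    "SimulationConfig",
    "SimulatedDistribution",
    "simulate_losses",
    "simulate_masks",
    "simulate_pindex",
    "calibrate_from_observed",
]


@dataclass
class SimulationConfig:
    """Geometry and loss parameters of a fractionation simulation.

    ``target_retention`` holds one retained fraction per subgenome;
    ``run_length_p`` is the geometric success parameter (mean run 1/p).
    Replicate r uses the independent seed ``seed + r``, so a distribution is
    bit-reproducible from (config, seed) with numpy's default PCG64 stream.
    """

    n_chromosomes: int = 10
    genes_per_chromosome: int = 2000
    S: int = 2
    target_retention: tuple[float, ...] = (0.6, 0.6)
    run_length_p: float = 0.5
    M: int = 100
    tau: float = 0.05
    replicates: int = 100
    seed: int = 1
    rng_algorithm: str = "numpy.random.PCG64"

    def __post_init__(self):
        self.target_retention = tuple(float(r) for r in self.target_retention)
        if len(self.target_retention) != self.S:
            raise ValueError(
                f"{len(self.target_retention)} retention targets for S={self.S}"
            )
        for r in self.target_retention:
            if not (0 < r <= 1):
                raise ValueError(f"target retention {r} outside (0, 1]")
        if not (0 < self.run_length_p <= 1):
            raise ValueError(f"run_length_p {self.run_length_p} outside (0, 1]")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")


@dataclass
class SimulatedDistribution:
    """Replicate P-index values with summary statistics and config echo."""

    values: np.ndarray
    config: SimulationConfig
    statuses: list[str] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.values, q))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": ["mean", "sd", "min", "q2.5", "q97.5", "max"],
                "value": [
                    self.mean,
                    self.sd,
                    float(self.values.min()),
                    self.quantile(0.025),
                    self.quantile(0.975),
                    float(self.values.max()),
                ],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"replicate": np.arange(1, len(self.values) + 1), "pindex": self.values}
        )


def simulate_losses(
    gene_count: int,
    target_retention: float,
    run_length_p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Delete genes in geometric runs until the target retention is reached.

    Returns a boolean mask over gene ranks (True = retained). Run starts are
    uniform over still-retained genes and runs consume only still-retained
    genes (truncated at the chromosome end), so the marginal run-length
    distribution on the retained sequence stays geometric. The final run may
    overshoot: the retained fraction ends within one run length below the
    target.
    """
    if not (0 < target_retention <= 1):
        raise ValueError(f"target retention {target_retention} outside (0, 1]")
    mask = np.ones(gene_count, dtype=bool)
    if target_retention == 1.0:
        return mask
    retained = gene_count
    target_count = target_retention * gene_count
    while retained > target_count:
        # uniform over retained genes via rejection (retention stays high)
        while True:
            start = int(rng.integers(gene_count))
            if mask[start]:
                break
        L = int(rng.geometric(run_length_p))
        pos = start
        while L > 0 and pos < gene_count:
            if mask[pos]:
                mask[pos] = False
                retained -= 1
                L -= 1
            pos += 1
    return mask


def simulate_masks(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One replicate's retention masks: chrom -> (S, n_genes) boolean array."""
    masks = {}
    for c in range(config.n_chromosomes):
        chrom = np.empty((config.S, config.genes_per_chromosome), dtype=bool)
        for k in range(config.S):
            chrom[k] = simulate_losses(
                config.genes_per_chromosome,
                config.target_retention[k],
                config.run_length_p,
                rng,
            )
        masks[f"chr{c + 1}"] = chrom
    return masks


def simulate_pindex(config: SimulationConfig) -> SimulatedDistribution:
    """Simulate the P-index distribution under the configured loss scenario.

    Each replicate fractionates an intact ancestor independently per
    subgenome, windows the masks against that ancestor and fits the
    (pair or multi) P-index.
    """
    values = np.empty(config.replicates)
    statuses = []
    for rep in range(config.replicates):
        rng = np.random.default_rng(config.seed + rep)
        masks = simulate_masks(config, rng)
        res = PIndexModel.from_masks(masks, M=config.M, tau=config.tau).fit()
        values[rep] = res.pindex
        statuses.append(res.status)
    return SimulatedDistribution(values=values, config=config, statuses=statuses)


def _lost_run_lengths(track: dict, n_genes: int) -> list[int]:
    retained = np.zeros(n_genes, dtype=bool)
    ranks = np.fromiter(track.keys(), dtype=int, count=len(track))
    retained[ranks] = True
    runs = []
    length = 0
    for flag in retained:
        if flag:
            if length:
                runs.append(length)
            length = 0
        else:
            length += 1
    if length:
        runs.append(length)
    return runs


def calibrate_from_observed(
    assignment,
    geometry: tuple[int, int] | None = None,
    balanced: bool = False,
    replicates: int = 100,
    seed: int = 1,
    M: int = 100,
    tau: float = 0.05,
) -> SimulationConfig:
    """Fit a simulation config to an observed subgenome assignment.

    Retention targets are the observed genome-wide retained fraction per
    track (or their pooled mean when ``balanced=True``); the geometric
    parameter is fitted by method of moments on observed lost-run lengths
    (p = 1 / mean run length). ``geometry`` overrides the simulated
    (n_chromosomes, genes_per_chromosome); by default the observed
    chromosome count and mean length are used.
    """
    import logging

    total = sum(assignment.n_genes.values())
    if total == 0:
        raise ValueError("assignment covers no genes")
    retained = assignment.retained_counts()
    r = retained / total
    if balanced:
        r = np.full(assignment.S, float(r.mean()))
    runs = []
    for chrom in assignment.chromosomes:
        for track in assignment.tracks[chrom]:
            runs.extend(_lost_run_lengths(track, assignment.n_genes[chrom]))
    if runs:
        p = 1.0 / float(np.mean(runs))
    else:
        logging.getLogger(__name__).warning(
            "no lost genes observed; defaulting run_length_p to 0.5"
        )
        p = 0.5
    if geometry is None:
        n_chrom = len(assignment.chromosomes)
        genes = int(round(total / n_chrom))
        geometry = (n_chrom, genes)
    r = tuple(min(1.0, max(1e-6, float(x))) for x in r)
    return SimulationConfig(
        n_chromosomes=geometry[0],
        genes_per_chromosome=geometry[1],
        S=assignment.S,
        target_retention=r,
        run_length_p=p,
        M=M,
        tau=tau,
        replicates=replicates,
        seed=seed,
    )
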