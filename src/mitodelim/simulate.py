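"""Synthetic control-region-like alignments with planted group structure.

The generator emulates the statistical shape the delimitation analysis
assumes: two (or more) groups with low within-group p-distance and
distinctly higher between-group p-distance, unequal group sizes, occasional
gaps, and a handful of fixed diagnostic differences between groups.

Model: a uniform-random ancestor; one founder per group obtained by
mutating each ancestral site with probability ``d_between`` (uniform choice
among the 3 alternative bases); each individual derived from its group
founder with per-site substitution probability ``d_within``; planted
diagnostic columns overwritten with distinct, within-group-monomorphic
bases; gaps injected independently at ``gap_rate``.  Substitutions are
site-independent with uniform alternatives (Jukes–Cantor-like) — the
simplest model consistent with a model-free p-distance analysis.

Defaults (group sizes 65/30, 733 columns, 6 diagnostic sites) copy the
shape of a real two-population shark control-region dataset, so tests run
under realistic cryptic-species conditions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .seqio import Alignment, write_fasta, write_labels

__all__ = ["SimConfig", "SimulatedDataset", "simulate", "expected_pdistance"]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the planted-group alignment generator.

    length:        alignment columns (bp)
    group_sizes:   sequences per group (unequal sizes allowed)
    d_within:      per-site substitution probability founder -> individual
    d_between:     per-site substitution probability ancestor -> founder,
                   applied independently on each group's branch
    gap_rate:      per-site gap probability per sequence
    n_diagnostic:  columns forced to a fixed inter-group difference
    seed:          master seed; the dataset is a pure function of it
    """

    length: int = 733
    group_sizes: tuple[int, ...] = (65, 30)
    d_within: float = 0.005
    d_between: float = 0.05
    gap_rate: float = 0.005
    n_diagnostic: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_sizes = tuple(int(g) for g in self.group_sizes)
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("every group needs at least one sequence")
        if self.n_diagnostic > self.length:
            raise ValueError("more diagnostic sites than alignment columns")
        if not (0 <= self.d_within < 1 and 0 <= self.d_between < 1):
            raise ValueError("substitution probabilities must lie in [0, 1)")
        if self.d_within >= self.d_between and self.d_between > 0:
            # cryptic-species premise: within-group variation below divergence
            raise ValueError("d_within must be smaller than d_between")


@dataclass
class SimulatedDataset:
    """A generated alignment plus its ground truth."""

    alignment: Alignment
    true_labels: list[str]
    planted_sites: list[int]  # 1-based alignment columns
    config: SimConfig = field(repr=False)

    def write(self, outdir: str | Path) -> None:
        """Write FASTA + labels TSV + planted-sites TSV + config JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.alignment, outdir / "alignment.fasta")
        write_labels(
            self.alignment.ids, self.true_labels, outdir / "labels.tsv"
        )
        with open(outdir / "planted_sites.tsv", "w") as fh:
            fh.write("column\n")
            for c in self.planted_sites:
                fh.write(f"{c}\n")
        with open(outdir / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability `rate`, uniform among the 3 others."""
    out = seq.copy()
    if rate <= 0:
        return out
    hit = np.nonzero(rng.random(seq.size) < rate)[0]
    # shift by 1..3 in base index space: uniform over the three alternatives
    out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def simulate(config: SimConfig | None = None, **kwargs) -> SimulatedDataset:
    """Generate a planted-group alignment; deterministic given the seed."""
    if config is None:
        config = SimConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SimConfig or keyword overrides")
    rng = np.random.default_rng(config.seed)
    L = config.length
    ancestor = rng.integers(0, 4, size=L)
    founders = [
        _mutate(ancestor, config.d_between, rng) for _ in config.group_sizes
    ]
    # diagnostic columns: every group monomorphic, all groups distinct
    planted = np.sort(
        rng.choice(L, size=config.n_diagnostic, replace=False)
    )
    if config.n_diagnostic:
        if len(config.group_sizes) > 4:
            raise ValueError(
                "cannot plant fixed differences for more than 4 groups"
            )
        for col in planted:
            order = rng.permutation(4)[: len(founders)]
            for f, base in zip(founders, order):
                f[col] = base

    seqs: list[str] = []
    ids: list[str] = []
    labels: list[str] = []
    for g, (size, founder) in enumerate(zip(config.group_sizes, founders)):
        gname = f"G{g + 1}"
        for k in range(size):
            ind = _mutate(founder, config.d_within, rng)
            if config.n_diagnostic:
                ind[planted] = founder[planted]  # keep diagnostics monomorphic
            chars = _BASES[ind]
            if config.gap_rate > 0:
                gaps = rng.random(L) < config.gap_rate
                gaps[planted] = False
                chars = chars.copy()
                chars[gaps] = "-"
            seqs.append("".join(chars))
            ids.append(f"{gname}_{k + 1:03d}")
            labels.append(gname)
    aln = Alignment(ids=ids, seqs=seqs, labels=list(labels))
    return SimulatedDataset(
        alignment=aln,
        true_labels=labels,
        planted_sites=[int(c) + 1 for c in planted],
        config=config,
    )


def expected_pdistance(config: SimConfig) -> tuple[float, float]:
    """Closed-form expected within- and between-group p-distances.

    Under the uniform-alternative substitution channel with per-site rate d,
    the probability of identity after one branch decays with eigenvalue
    lam(d) = 1 − 4d/3, and for a path through k branches the expected
    site-difference probability is 3/4 · (1 − prod lam).  Within-group pairs
    are separated by two d_within branches; between-group pairs by two
    d_between plus two d_within branches.  Planted diagnostic columns are
    monomorphic within groups (contribute 0 within, 1 between); gaps are
    excluded pairwise and do not bias the proportion.
    """
    lam_w = 1.0 - 4.0 * config.d_within / 3.0
    lam_b = 1.0 - 4.0 * config.d_between / 3.0
    p_within_site = 0.75 * (1.0 - lam_w**2)
    p_between_site = 0.75 * (1.0 - lam_w**2 * lam_b**2)
    frac_diag = config.n_diagnostic / config.length
    within = (1.0 - frac_diag) * p_within_site
    between = (1.0 - frac_diag) * p_between_site + frac_diag * 1.0
    return within, between
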