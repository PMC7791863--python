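"""Neutral community assembly simulators and test-fixture generators.

Two routes to the same stationary behaviour:

* ``simulate_beta_multinomial`` draws each local community's composition
  directly from the stationary Dirichlet(N*m*p) approximation of the
  neutral model (whose per-taxon marginals are Beta(N m p_i, N m (1-p_i)))
  and then samples reads multinomially — fast, used for fixtures.
* ``simulate_moran`` runs the individual-based dynamics: per step one
  resident dies and is replaced by a source-pool immigrant with
  probability m, otherwise by the offspring of a surviving resident —
  the mechanistic counterpart, used to validate the approximation.

Sequencing depth (``reads_per_sample``) is deliberately decoupled from
the ecological community size N: reads are not individuals.

Also houses fixture generators for FASTQ read sets with recorded
per-read truth and for two-class count tables with spiked
differentially abundant features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gutneutral.otu_io import OtuTable

SourceGenerator = Literal["logseries", "dirichlet", "explicit"]


@dataclass
class SourceCommunity:
    """Source (meta)community relative abundances feeding immigration."""

    otu_ids: list[str]
    p: np.ndarray
    generator: str = "explicit"

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p <= 0):
            raise ValueError("source abundances must all be positive")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("source abundances must sum to 1")
        if len(self.otu_ids) != len(self.p):
            raise ValueError("otu_ids and p must have equal length")


@dataclass
class SimConfig:
    """Parameters of a neutral-assembly run.

    ``community_size_N`` is the number of individuals in each local
    community; ``reads_per_sample`` the sequencing depth (defaults to N
    when left at 0). ``burn_in_generations`` applies to moran mode only;
    one generation is N replacement events.
    """

    n_samples: int
    community_size_N: int
    m: float
    reads_per_sample: int = 0
    mode: Literal["moran", "beta_multinomial"] = "beta_multinomial"
    burn_in_generations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_sample == 0:
            self.reads_per_sample = self.community_size_N
        if self.n_samples < 1 or self.community_size_N < 1 or self.reads_per_sample < 1:
            raise ValueError("sample count, community size and depth must be positive")
        if not 0 < self.m <= 1:
            raise ValueError("m must lie in (0, 1]")
        if self.burn_in_generations < 1:
            raise ValueError("burn_in_generations must be >= 1")


def sample_source(
    n_otus: int,
    generator: SourceGenerator = "logseries",
    params: dict | None = None,
    seed: int = 0,
) -> SourceCommunity:
    """Draw a source community abundance vector.

    ``logseries`` (default) gives the long-tailed, few-dominants shape
    typical of gut communities (parameter ``theta`` in (0,1), default
    0.999); ``dirichlet`` gives flatter communities (``alpha`` default
    1.0); ``explicit`` normalizes a user vector given as ``params["p"]``.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    otu_ids = [f"OTU_{i + 1}" for i in range(n_otus)]
    if generator == "logseries":
        theta = float(params.get("theta", 0.999))
        k = stats.logser.rvs(theta, size=n_otus, random_state=rng).astype(float)
        p = k / k.sum()
    elif generator == "dirichlet":
        alpha = float(params.get("alpha", 1.0))
        p = rng.dirichlet(np.full(n_otus, alpha))
        p = np.maximum(p, 1e-15)
        p = p / p.sum()
    elif generator == "explicit":
        v = np.asarray(params["p"], dtype=float)
        if np.any(v <= 0):
            raise ValueError("explicit abundances must all be positive")
        p = v / v.sum()
        if len(p) != n_otus:
            raise ValueError("explicit vector length must equal n_otus")
    else:
        raise ValueError(f"unknown generator {generator!r}")
    return SourceCommunity(otu_ids=otu_ids, p=p, generator=generator)


def _multinomial_rows(rng: np.random.Generator, depth: int, probs: np.ndarray) -> np.ndarray:
    out = np.empty(probs.shape, dtype=np.int64)
    for i in range(probs.shape[0]):
        row = probs[i] / probs[i].sum()
        out[i] = rng.multinomial(depth, row)
    return out


def _as_table(counts: np.ndarray, source: SourceCommunity, prefix: str = "S") -> OtuTable:
    sample_ids = [f"{prefix}{i + 1}" for i in range(counts.shape[0])]
    return OtuTable(sample_ids=sample_ids, otu_ids=list(source.otu_ids), counts=counts)


def simulate_beta_multinomial(source: SourceCommunity, config: SimConfig) -> OtuTable:
    """Sample local communities from the stationary Dirichlet approximation.

    Per sample the composition is Dirichlet with concentration N*m*p and
    reads are drawn multinomially at ``reads_per_sample``; every row sums
    to the configured depth exactly.
    """
    rng = np.random.default_rng(config.seed)
    alpha = config.community_size_N * config.m * source.p
    # gamma representation keeps tiny concentrations (rare taxa) stable
    g = rng.gamma(shape=np.broadcast_to(alpha, (config.n_samples, len(alpha))))
    totals = g.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    probs = g / totals
    counts = _multinomial_rows(rng, config.reads_per_sample, probs)
    return _as_table(counts, source)


def stationary_compositions(
    source: SourceCommunity, config: SimConfig
) -> np.ndarray:
    """Dirichlet stationary compositions without read sampling (samples x OTUs)."""
    rng = np.random.default_rng(config.seed)
    alpha = config.community_size_N * config.m * source.p
    g = rng.gamma(shape=np.broadcast_to(alpha, (config.n_samples, len(alpha))))
    totals = g.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return g / totals


def simulate_moran(
    source: SourceCommunity, config: SimConfig, return_counts_matrix: bool = False
) -> OtuTable | np.ndarray:
    """Individual-based neutral dynamics, vectorized over communities.

    Each community holds exactly ``community_size_N`` individuals. Per
    replacement event a uniformly chosen resident dies; the slot is filled
    by an immigrant drawn from the source pool with probability m, else by
    the offspring of a uniformly chosen surviving resident. One generation
    is N events. Communities start as independent multinomial draws from
    the source and run for ``burn_in_generations`` generations before
    counts are reported (multinomially subsampled to ``reads_per_sample``
    when that differs from N).
    """
    if config.mode != "moran":
        raise ValueError("config.mode must be 'moran'")
    rng = np.random.default_rng(config.seed)
    S, N, K = config.n_samples, config.community_size_N, len(source.p)
    cdf = np.cumsum(source.p)
    cdf[-1] = 1.0
    # labels[s, slot] = OTU index of the individual in that slot
    labels = np.searchsorted(cdf, rng.random((S, N))).astype(np.int32)
    rows = np.arange(S)
    n_steps = config.burn_in_generations * N
    for _ in range(n_steps):
        death = rng.integers(N, size=S)
        immigrate = rng.random(S) < config.m
        new = np.empty(S, dtype=np.int32)
        n_imm = int(immigrate.sum())
        if n_imm:
            new[immigrate] = np.searchsorted(cdf, rng.random(n_imm))
        local = ~immigrate
        if local.any():
            # parent uniformly among the N-1 survivors (skip the dead slot)
            j = rng.integers(N - 1, size=S)
            parent = j + (j >= death)
            new[local] = labels[rows[local], parent[local]]
        labels[rows, death] = new
    counts = np.zeros((S, K), dtype=np.int64)
    np.add.at(counts, (np.repeat(rows, N), labels.ravel()), 1)
    if config.reads_per_sample != N:
        counts = _multinomial_rows(rng, config.reads_per_sample, counts.astype(float))
    if return_counts_matrix:
        return counts
    return _as_table(counts, source)


STUDY_GROUPS: dict[str, tuple[int, float]] = {
    # group -> (number of gut communities, immigration rate)
    "Control": (10, 0.017),
    "N_lim": (7, 0.038),
    "P_lim": (12, 0.023),
}


def make_study_fixture(
    seed: int = 0,
    n_otus: int = 300,
    depth: int = 1000,
    community_size: int = 1000,
) -> OtuTable:
    """Emulate the 29-gut study design on synthetic data.

    One shared log-series source community; per diet group, gut
    communities are sampled from the stationary neutral approximation at
    that group's immigration rate: Control 10 guts at m = 0.017,
    N limitation 7 at m = 0.038, P limitation 12 at m = 0.023. Group
    labels are attached to the returned table.
    """
    source = sample_source(n_otus, "logseries", seed=seed)
    all_counts = []
    sample_ids: list[str] = []
    group: dict[str, str] = {}
    for gi, (label, (n, m)) in enumerate(STUDY_GROUPS.items()):
        cfg = SimConfig(
            n_samples=n,
            community_size_N=community_size,
            reads_per_sample=depth,
            m=m,
            mode="beta_multinomial",
            seed=seed * 7919 + gi + 1,
        )
        t = simulate_beta_multinomial(source, cfg)
        all_counts.append(t.counts)
        for s in t.sample_ids:
            sid = f"{label}_{s}"
            sample_ids.append(sid)
            group[sid] = label
    return OtuTable(
        sample_ids=sample_ids,
        otu_ids=list(source.otu_ids),
        counts=np.vstack(all_counts),
        group=group,
    )


_BASES = np.array(list("ACGT"))


def _longest_run_below(quals: np.ndarray, thresh: int) -> int:
    run = best = 0
    for q in quals:
        if q < thresh:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def make_fastq_fixture(
    n_reads: int = 200,
    length_range: tuple[int, int] = (120, 170),
    quality_profile: tuple[float, float] = (32.0, 6.0),
    n_rate: float = 0.002,
    with_primers: bool = False,
    seed: int = 0,
    fwd_primer: str = "CCTACGGGRSGCAGCAG",
    rev_primer: str = "CTACNRGGGTATCTAA",
    out_fastq: str | Path | None = None,
    out_truth: str | Path | None = None,
):
    """Generate synthetic reads with a recorded per-read truth table.

    Lengths are uniform over ``length_range`` (straddling the 135-152 bp
    window so both outcomes occur); per-read mean quality is normal with
    the given (mean, sd); per-base qualities jitter around the read mean;
    each base is replaced by N at rate ``n_rate``. With ``with_primers``
    half the reads (recorded in the truth) carry the forward primer as a
    prefix and the reverse complement of the reverse primer as a suffix,
    with degenerate positions resolved randomly.

    Returns ``(reads, truth)`` where reads are
    :class:`~gutneutral.amplicon_qc.ReadRecord` and truth is a DataFrame
    with one row per read: length, mean_q, min_q, longest_lowq_run,
    n_count, has_primers and an independently computed ``all_pass`` flag
    for the default thresholds.
    """
    from gutneutral.amplicon_qc import IUPAC_SETS, ReadRecord, reverse_complement

    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    rows = []
    lo, hi = length_range
    for i in range(n_reads):
        length = int(rng.integers(lo, hi + 1))
        mean_q = float(rng.normal(*quality_profile))
        quals = np.clip(np.round(rng.normal(mean_q, 3.0, size=length)), 2, 41).astype(int)
        if rng.random() < 0.15:  # occasional low-quality dip
            start = int(rng.integers(0, max(1, length - 6)))
            run_len = int(rng.integers(2, 7))
            quals[start : start + run_len] = rng.integers(5, 20, size=min(run_len, length - start))
        seq = rng.choice(_BASES, size=length)
        n_mask = rng.random(length) < n_rate
        seq[n_mask] = "N"
        sequence = "".join(seq)
        has_primers = False
        if with_primers and rng.random() < 0.5:
            has_primers = True
            fwd = "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in fwd_primer)
            rev = "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in reverse_complement(rev_primer))
            sequence = fwd + sequence + rev
            quals = np.concatenate(
                [np.full(len(fwd), 38), quals, np.full(len(rev), 38)]
            )
        quals_list = [int(q) for q in quals]
        reads.append(ReadRecord(id=f"read_{i + 1}", sequence=sequence, quals=quals_list))
        # truth stats refer to the insert (post-trim coordinates)
        insert_q = np.asarray(quals_list)
        insert_seq = sequence
        if has_primers:
            insert_q = insert_q[len(fwd) : len(insert_q) - len(rev)]
            insert_seq = sequence[len(fwd) : len(sequence) - len(rev)]
        L = len(insert_seq)
        mq = float(insert_q.mean())
        run = _longest_run_below(insert_q, 25)
        minq = int(insert_q.min())
        n_count = insert_seq.count("N")
        all_pass = (
            135 <= L <= 152
            and mq >= 25.0
            and run <= 3
            and minq >= 3
            and (insert_q >= 25).mean() >= 0.75
            and n_count == 0
        )
        rows.append(
            {
                "read_id": f"read_{i + 1}",
                "length": L,
                "mean_q": mq,
                "min_q": minq,
                "longest_lowq_run": run,
                "n_count": n_count,
                "has_primers": has_primers,
                "all_pass": bool(all_pass),
            }
        )
    truth = pd.DataFrame(rows)
    if out_fastq is not None:
        from gutneutral.amplicon_qc import write_fastq

        write_fastq(reads, out_fastq)
    if out_truth is not None:
        truth.to_csv(out_truth, sep="\t", index=False)
    return reads, truth


def make_diffabund_fixture(
    n_features: int = 100,
    n_per_class: tuple[int, int] = (20, 20),
    spiked: Sequence[tuple[int, float]] = (),
    seed: int = 0,
    depth_mean: float = 1e4,
    dispersion: float = 5.0,
):
    """Two-class count table with spiked differentially abundant features.

    Unspiked features share one negative-binomial law across classes
    (lognormal baseline means, gamma-Poisson counts with the given
    dispersion); each ``(feature_index, fold_change)`` entry multiplies
    that feature's mean in class B. Returns ``(table, truth)`` where
    truth is the dict feature_id -> fold_change of spiked features and
    the table carries class labels "A"/"B" in its group map.
    """
    for _, fc in spiked:
        if fc <= 0:
            raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    n_a, n_b = n_per_class
    base_mean = rng.lognormal(mean=np.log(depth_mean / n_features), sigma=1.0, size=n_features)
    mean_a = base_mean.copy()
    mean_b = base_mean.copy()
    truth: dict[str, float] = {}
    for idx, fc in spiked:
        mean_b[idx] = mean_b[idx] * fc
        truth[f"OTU_{idx + 1}"] = fc

    def _draw(means: np.ndarray, n: int) -> np.ndarray:
        r = dispersion
        p = r / (r + means)
        return rng.negative_binomial(r, p, size=(n, len(means)))

    counts = np.vstack([_draw(mean_a, n_a), _draw(mean_b, n_b)])
    sample_ids = [f"A_{i + 1}" for i in range(n_a)] + [f"B_{i + 1}" for i in range(n_b)]
    group = {s: s.split("_")[0] for s in sample_ids}
    table = OtuTable(
        sample_ids=sample_ids,
        otu_ids=[f"OTU_{j + 1}" for j in range(n_features)],
        counts=counts,
        group=group,
    )
    return table, truth
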