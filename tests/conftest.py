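import numpy as np
import pytest

from heartenh.intervals import GenomicInterval, IntervalSet
from heartenh.pipeline import RunConfig, run_all
from heartenh.synthetic_data import GeneratorConfig, generate


# ---------------------------------------------------------------------------
# per-base boolean-array oracle for interval algebra

class BaseOracle:
    """Exact per-base reference for merge/subtract/overlap on small coords."""

    def __init__(self, universe: int = 20_000):
        self.universe = universe

    def cover(self, s: IntervalSet) -> dict[str, np.ndarray]:
        cov: dict[str, np.ndarray] = {}
        for iv in s:
            arr = cov.setdefault(iv.chrom, np.zeros(self.universe, dtype=bool))
            arr[iv.start:iv.end] = True
        return cov

    def to_intervals(self, cov: dict[str, np.ndarray], assembly: str) -> IntervalSet:
        out = []
        for chrom in sorted(cov):
            arr = cov[chrom].astype(np.int8)
            edges = np.flatnonzero(np.diff(np.concatenate(([0], arr, [0]))))
            for lo, hi in zip(edges[::2], edges[1::2]):
                out.append(GenomicInterval(chrom, int(lo), int(hi), assembly))
        return IntervalSet(out, assembly)

    def merge(self, s: IntervalSet) -> IntervalSet:
        return self.to_intervals(self.cover(s), s.assembly)

    def subtract(self, a: IntervalSet, b: IntervalSet) -> IntervalSet:
        ca, cb = self.cover(a), self.cover(b)
        out = {}
        for chrom, arr in ca.items():
            out[chrom] = arr & ~cb.get(chrom, np.zeros(self.universe, dtype=bool))
        return self.to_intervals(out, a.assembly)

    def overlap(self, a: GenomicInterval, b: GenomicInterval) -> int:
        if a.chrom != b.chrom:
            return 0
        x = np.zeros(self.universe, dtype=bool)
        y = np.zeros(self.universe, dtype=bool)
        x[a.start:a.end] = True
        y[b.start:b.end] = True
        return int((x & y).sum())


@pytest.fixture(scope="session")
def oracle():
    return BaseOracle()


def random_interval_set(rng, n_max=200, coord_max=10_000, assembly="asmA",
                        chroms=("chr1", "chr2")):
    n = int(rng.integers(0, n_max + 1))
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, coord_max - 1))
        end = int(rng.integers(start + 1, coord_max))
        out.append(GenomicInterval(chrom, start, end, assembly))
    return IntervalSet(out, assembly)


# ---------------------------------------------------------------------------
# shared synthetic worlds (session-scoped: the pipeline runs in ~1 s)

@pytest.fixture(scope="session")
def default_world(tmp_path_factory):
    """The default synthetic study conditions, seed 1."""
    d = tmp_path_factory.mktemp("world_default")
    return generate(GeneratorConfig(), seed=1, out_dir=str(d))


@pytest.fixture(scope="session")
def default_run(default_world, tmp_path_factory):
    out = tmp_path_factory.mktemp("run_default")
    return run_all(RunConfig.from_world(default_world, str(out)))


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    """A reduced world for fast unit-level checks."""
    cfg = GeneratorConfig(n_chroms=1, chrom_length=2_000_000, n_enhancers=40,
                          n_genes=20, n_blacklist=4,
                          n_validation_planted=30, n_validation_background=15,
                          n_lead_snps=10)
    d = tmp_path_factory.mktemp("world_small")
    return generate(cfg, seed=11, out_dir=str(d))
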