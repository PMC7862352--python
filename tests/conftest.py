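import numpy as np
import pandas as pd
import pytest

from chrombarcode import (
    GeneAnnotation,
    GenomeLayout,
    ReadCollection,
    SampleMeta,
    build_default_model,
    simulate_reads,
)

DEPTH = 1_000_000


@pytest.fixture(scope="session")
def model20():
    """Default 20 Mb one-chromosome model (bands, genes, TADs, phase effects)."""
    return build_default_model(1, 20_000_000, "LCL", seed=1)


@pytest.fixture(scope="session")
def model20_no_phase():
    """Same layout but without any phase effects (cross-phase null)."""
    return build_default_model(1, 20_000_000, "LCL", seed=1, phase_effects={})


@pytest.fixture(scope="session")
def k9_g1(model20):
    return simulate_reads(model20, "H3K9ac", "G1", DEPTH, seed=11)


@pytest.fixture(scope="session")
def k9_g2m(model20):
    return simulate_reads(model20, "H3K9ac", "G2M", DEPTH, seed=12)


@pytest.fixture
def tiny_layout():
    return GenomeLayout((("chr1", 20_000), ("chr2", 12_000)))


def make_reads(layout, triples, meta=None):
    """Build a ReadCollection from (chrom, start, end[, strand]) tuples."""
    cidx, s, e, st = [], [], [], []
    for t in triples:
        cidx.append(layout.index(t[0]))
        s.append(t[1])
        e.append(t[2])
        st.append(t[3] if len(t) > 3 else ".")
    return ReadCollection(
        layout,
        np.asarray(cidx, dtype=np.int32),
        np.asarray(s, dtype=np.int64),
        np.asarray(e, dtype=np.int64),
        np.asarray(st, dtype="<U1"),
        meta or SampleMeta(total_reads=len(s)),
    )


def make_genes(rows):
    """rows: (gene_id, chrom, start, end, strand[, classes])"""
    recs = []
    for r in rows:
        classes = frozenset(r[5]) if len(r) > 5 else frozenset()
        recs.append((r[0], r[1], r[2], r[3], r[4], classes))
    return GeneAnnotation(
        pd.DataFrame(recs, columns=["gene_id", "chrom", "start", "end", "strand", "classes"])
    )


def brute_force_window_counts(reads, grid, mode):
    """O(n*m) reference scan for count_reads, both modes."""
    raw = np.zeros(len(grid), dtype=np.int64)
    for j in range(len(grid)):
        ws, we, wc = grid.start[j], grid.end[j], grid.chrom_idx[j]
        for i in range(len(reads)):
            if reads.chrom_idx[i] != wc:
                continue
            s, e = reads.start[i], reads.end[i]
            if mode == "midpoint":
                m = (s + e) // 2
                if ws <= m < ws + grid.W:
                    raw[j] += 1
            else:
                if max(s, ws) < min(e, we):
                    raw[j] += 1
    return raw


def brute_force_interval_counts(reads, intervals):
    """Reference midpoint-in-interval counts."""
    df = intervals.df.reset_index(drop=True)
    out = np.zeros(len(df), dtype=np.int64)
    names = reads.layout.names
    for j, row in df.iterrows():
        for i in range(len(reads)):
            if names[reads.chrom_idx[i]] != row["chrom"]:
                continue
            m = (reads.start[i] + reads.end[i]) // 2
            if row["start"] <= m < row["end"]:
                out[j] += 1
    return out
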