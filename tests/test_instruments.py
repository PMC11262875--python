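"""Instrument selection, clumping (with brute-force oracle) and strength."""

import itertools

import numpy as np
import pytest

from mrlink.instruments import (
    LDPair,
    clump,
    exclude_confounder_associated,
    f_statistic,
    select_by_pvalue,
    strength_table,
    variance_explained,
)
from mrlink.io import SummaryRecord


def rec(snp, p, chrom="1", pos=1, se=0.02):
    return SummaryRecord(snp, "A", "C", 0.3, 0.1, se, p, 1000, chrom=chrom, pos=pos)


# ---------------------------------------------------------------- selection

def test_published_instruments_all_pass_genome_wide_threshold(ra_instruments):
    assert len(select_by_pvalue(ra_instruments, 5e-8)) == 5


def test_threshold_zero_keeps_nothing(ra_instruments):
    assert select_by_pvalue(ra_instruments, 0.0) == []


def test_selection_matches_direct_filter_oracle():
    rng = np.random.default_rng(42)
    records = [rec(f"rs{i}", float(p)) for i, p in enumerate(rng.uniform(size=100))]
    kept = select_by_pvalue(records, 0.5)
    assert kept == [r for r in records if r.pval < 0.5]


# ----------------------------------------------------------------- clumping

def test_correlated_nearby_pair_pruned_to_smaller_p():
    a, b = rec("rsA", 1e-10, pos=1_000_000), rec("rsB", 1e-9, pos=6_000_000)
    kept = clump([a, b], [LDPair("rsA", "rsB", 0.5)], r2_threshold=0.001, window_kb=10_000)
    assert kept == [a]


def test_pair_outside_window_both_kept_despite_ld():
    a, b = rec("rsA", 1e-10, pos=1_000_000), rec("rsB", 1e-9, pos=21_000_000)
    kept = clump([a, b], [LDPair("rsA", "rsB", 0.5)], r2_threshold=0.001, window_kb=10_000)
    assert {r.snp_id for r in kept} == {"rsA", "rsB"}


def test_window_boundary_is_inclusive():
    a, b = rec("rsA", 1e-10, pos=1_000_000), rec("rsB", 1e-9, pos=11_000_000)
    kept = clump([a, b], [LDPair("rsA", "rsB", 0.9)], r2_threshold=0.001, window_kb=10_000)
    assert kept == [a]


def test_clump_requires_positions():
    bare = SummaryRecord("rs1", "A", "C", 0.3, 0.1, 0.02, 1e-9, 1000)
    with pytest.raises(ValueError, match="chrom/pos"):
        clump([bare], [], 0.001, 10_000)


def clump_oracle(records, ld, r2_threshold, window_kb):
    """Exhaustive reference: among all maximal conflict-free subsets, the one
    that is lexicographically first in (p, se, rsID) order — which is what
    greedy index selection must return."""
    order = sorted(range(len(records)), key=lambda i: (records[i].pval, records[i].se, records[i].snp_id))
    rank = {i: order.index(i) for i in range(len(records))}
    lookup = {}
    for pair in ld:
        lookup[frozenset((pair.snp_a, pair.snp_b))] = max(
            lookup.get(frozenset((pair.snp_a, pair.snp_b)), 0.0), pair.r2
        )

    def conflict(i, j):
        a, b = records[i], records[j]
        if a.chrom != b.chrom or abs(a.pos - b.pos) > window_kb * 1000:
            return False
        return lookup.get(frozenset((a.snp_id, b.snp_id)), 0.0) >= r2_threshold

    n = len(records)
    conflicts = [set(j for j in range(n) if j != i and conflict(i, j)) for i in range(n)]
    best = None
    for subset in itertools.chain.from_iterable(
        itertools.combinations(range(n), k) for k in range(n + 1)
    ):
        chosen = set(subset)
        if any(j in conflicts[i] for i in chosen for j in chosen):
            continue
        if any(not (conflicts[j] & chosen) for j in range(n) if j not in chosen):
            continue  # not maximal: some outside SNP could be added
        key = tuple(sorted(rank[i] for i in chosen))
        if best is None or key < best[0]:
            best = (key, chosen)
    chosen = best[1]
    return sorted((records[i] for i in chosen), key=lambda r: (r.pval, r.se, r.snp_id))


def _random_instance(rng, n):
    chroms = rng.integers(1, 4, size=n)  # 3 chromosomes -> 3 potential LD blocks
    positions = rng.integers(1, 30_000_000, size=n)
    records = [
        rec(f"rs{i}", float(rng.uniform()), chrom=str(chroms[i]), pos=int(positions[i]))
        for i in range(n)
    ]
    ld = []
    for i in range(n):
        for j in range(i + 1, n):
            if chroms[i] == chroms[j] and rng.random() < 0.6:
                ld.append(LDPair(f"rs{i}", f"rs{j}", float(rng.uniform())))
    return records, ld


@pytest.mark.parametrize("seed", range(15))
def test_clump_matches_bruteforce_oracle_small_instances(seed):
    rng = np.random.default_rng(seed)
    records, ld = _random_instance(rng, int(rng.integers(4, 11)))
    got = clump(records, ld, r2_threshold=0.3, window_kb=10_000)
    want = clump_oracle(records, ld, 0.3, 10_000)
    assert [r.snp_id for r in got] == [r.snp_id for r in want]


@pytest.mark.parametrize("seed", range(5))
def test_clumped_output_pairwise_valid(seed):
    rng = np.random.default_rng(100 + seed)
    records, ld = _random_instance(rng, 12)
    lookup = {frozenset((p.snp_a, p.snp_b)): p.r2 for p in ld}
    kept = clump(records, ld, r2_threshold=0.3, window_kb=10_000)
    for a, b in itertools.combinations(kept, 2):
        within = a.chrom == b.chrom and abs(a.pos - b.pos) <= 10_000 * 1000
        r2 = lookup.get(frozenset((a.snp_id, b.snp_id)), 0.0)
        assert not (within and r2 >= 0.3)


# ----------------------------------------------------- confounder screening

def test_confounder_annotated_snp_excluded():
    records = [rec("rs1", 1e-9), rec("rs2", 1e-9)]
    kept, removed = exclude_confounder_associated(
        records,
        {"rs1": ["Hypertension"]},
        ["CAD", "hypertension", "BMI"],
    )
    assert [r.snp_id for r in kept] == ["rs2"]
    assert removed[0] == ("rs1", "Hypertension")


def test_empty_annotation_table_is_identity():
    records = [rec("rs1", 1e-9)]
    kept, removed = exclude_confounder_associated(records, {}, ["CAD"])
    assert kept == records and removed == []


def test_confounder_screen_matches_set_difference_oracle():
    rng = np.random.default_rng(7)
    records = [rec(f"rs{i}", 1e-9) for i in range(20)]
    flagged = rng.choice(20, size=7, replace=False)
    annotations = {f"rs{i}": ["body mass index"] for i in flagged}
    kept, removed = exclude_confounder_associated(records, annotations, ["BMI", "body mass index"])
    assert len(kept) == 13
    assert {r.snp_id for r in kept} == {r.snp_id for r in records} - set(annotations)


# ------------------------------------------------------ strength statistics

@pytest.mark.parametrize(
    "beta,eaf,expected",
    [(0.1857, 0.2392, 0.0126), (0.1505, 0.3029, 0.0096)],
)
def test_variance_explained_matches_printed_values(beta, eaf, expected):
    assert round(variance_explained(beta, eaf), 4) == expected


def test_variance_explained_symmetries():
    assert variance_explained(0.2, 0.0) == 0.0
    assert variance_explained(0.2, 0.3) == pytest.approx(variance_explained(0.2, 0.7))
    assert variance_explained(-0.2, 0.3) == pytest.approx(variance_explained(0.2, 0.3))


def test_f_statistic_formula_and_edge_cases():
    r2 = variance_explained(0.2123, 0.1068)  # unrounded
    assert f_statistic(r2, 212_453, 5) == pytest.approx(1843, abs=1)
    r2b = variance_explained(0.2074, 0.1158)
    assert f_statistic(r2b, 212_453, 5) == pytest.approx(1888, abs=1)
    assert f_statistic(0.0, 100, 1) == 0.0
    with pytest.raises(ValueError):
        f_statistic(1.0, 100, 1)
    with pytest.raises(ValueError):
        f_statistic(0.1, 5, 5)


def test_published_instrument_strength_summary(ra_instruments):
    strengths = strength_table(ra_instruments)  # K defaults to all 5
    # the printed per-SNP values sum to 0.0487; both roundings give "4.9%"
    assert sum(round(s.r_squared, 4) for s in strengths) == pytest.approx(0.0487)
    total = sum(s.r_squared for s in strengths)
    assert round(100 * total, 1) == 4.9
    assert all(s.f_stat > 10 for s in strengths)
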