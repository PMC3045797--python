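"""PSL/BED12 ingestion, metrics, best-hit selection, positional profile."""
import numpy as np
import pytest

from splicetrap.alignment_filter import (
    AlignedAsset,
    best_hit,
    classify_exon_count,
    filter_alignments,
    read_alignments,
    relative_position_profile,
    write_psl,
)
from splicetrap.genomic_model import GenomicInterval, TranscriptModel

from conftest import make_model


def make_asset(
    asset_id="a1",
    exons=((100, 200), (300, 400)),
    matches=95,
    aligned=100,
    qsize=120,
    chrom="chr1",
    strand="+",
):
    chain = make_model(list(exons), strand=strand, chrom=chrom, tid=asset_id)
    return AlignedAsset(asset_id, chain, matches, aligned, qsize)


def psl_line(
    qname="a1", matches=95, mismatches=5, qsize=120, chrom="chr1",
    strand="+", sizes=(50, 50), tstarts=(100, 300),
):
    aligned = matches + mismatches
    qstarts = np.cumsum([0] + list(sizes[:-1]))
    return "\t".join(
        str(x)
        for x in [
            matches, mismatches, 0, 0, 0, qsize - aligned, 0,
            tstarts[-1] + sizes[-1] - tstarts[0] - sum(sizes),
            strand, qname, qsize, 0, aligned, chrom, 10000,
            tstarts[0], tstarts[-1] + sizes[-1], len(sizes),
            ",".join(map(str, sizes)) + ",",
            ",".join(map(str, qstarts)) + ",",
            ",".join(map(str, tstarts)) + ",",
        ]
    )


class TestReadAlignments:
    def test_psl_metrics_from_direct_formula(self, tmp_path):
        p = tmp_path / "a.psl"
        p.write_text(psl_line() + "\n")
        (asset,) = read_alignments(p, "psl")
        assert asset.identity == pytest.approx(95.0)
        assert asset.coverage == pytest.approx(100 * 100 / 120)
        assert asset.n_exons == 2

    def test_random_psl_metrics_match_field_arithmetic(self, tmp_path, rng):
        lines = []
        expected = []
        for i in range(30):
            sizes = tuple(int(s) for s in rng.integers(20, 80, size=2))
            aligned = sum(sizes)
            matches = int(rng.integers(aligned // 2, aligned + 1))
            qsize = aligned + int(rng.integers(0, 50))
            lines.append(
                psl_line(
                    f"q{i}", matches, aligned - matches, qsize,
                    sizes=sizes, tstarts=(100, 100 + sizes[0] + 50),
                )
            )
            expected.append((100.0 * matches / aligned, 100.0 * aligned / qsize))
        p = tmp_path / "a.psl"
        p.write_text("\n".join(lines) + "\n")
        assets = read_alignments(p, "psl")
        for asset, (ident, cov) in zip(assets, expected):
            assert asset.identity == pytest.approx(ident)
            assert asset.coverage == pytest.approx(cov)

    def test_psl_write_read_round_trip(self, tmp_path):
        assets = [
            make_asset("b", matches=90, aligned=100, qsize=110),
            make_asset("a", exons=((10, 60),), matches=50, aligned=50, qsize=80),
        ]
        p = tmp_path / "out.psl"
        write_psl(assets, p)
        back = read_alignments(p, "psl")
        assert [a.asset_id for a in back] == ["a", "b"]
        for orig in assets:
            rt = next(a for a in back if a.asset_id == orig.asset_id)
            assert rt.matches == orig.matches
            assert rt.aligned_length == orig.aligned_length
            assert rt.query_length == orig.query_length
            assert rt.chain.exons == orig.chain.exons

    def test_bed12_requires_metrics_for_every_asset(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t400\tax\t0\t+\t100\t400\t0\t2\t100,100\t0,200\n")
        metrics = tmp_path / "m.tsv"
        metrics.write_text("asset_id\tmatches\taligned_length\tquery_length\nother\t1\t2\t3\n")
        with pytest.raises(ValueError, match="ax"):
            read_alignments(bed, "bed12", metrics)

    def test_strand_flip_leaves_metrics_invariant(self, tmp_path):
        p = tmp_path / "a.psl"
        p.write_text(psl_line(strand="+") + "\n" + psl_line("a2", strand="-") + "\n")
        plus, minus = read_alignments(p, "psl")
        assert plus.identity == minus.identity
        assert plus.coverage == minus.coverage


class TestBestHit:
    def test_single_alignment_is_its_own_best(self):
        a = make_asset()
        assert best_hit([a]) is a

    def test_more_matches_wins(self):
        lo = make_asset("x", matches=95, aligned=100)
        hi = make_asset("x", matches=98, aligned=100)
        assert best_hit([lo, hi]) is hi

    def test_matches_identity_coverage_then_position(self, rng):
        # randomized hit sets agree with an exhaustive max under the key
        for _ in range(20):
            hits = []
            for i in range(int(rng.integers(2, 6))):
                aligned = int(rng.integers(50, 120))
                matches = int(rng.integers(30, aligned + 1))
                start = int(rng.integers(0, 5000))
                hits.append(
                    make_asset(
                        "q", exons=((start, start + aligned),),
                        matches=matches, aligned=aligned,
                        qsize=aligned + 10, chrom=f"chr{int(rng.integers(1, 3))}",
                    )
                )
            exhaustive = max(
                hits,
                key=lambda a: (
                    a.matches, a.identity, a.coverage,
                    # invert the positional tie-break for max()
                    tuple(-ord(c) for c in a.chain.chrom), -a.chain.span.start,
                ),
            )
            assert best_hit(hits) is exhaustive


class TestFilter:
    def test_inclusive_boundaries(self):
        at_cut = make_asset("a", matches=1023, aligned=1100, qsize=2000)
        assert at_cut.identity == pytest.approx(93.0)
        assert at_cut.coverage == pytest.approx(55.0)
        kept = filter_alignments([at_cut], 93.0, 55.0)
        assert kept == [at_cut]

    def test_below_identity_dropped(self):
        low = make_asset("a", matches=92, aligned=100, qsize=120)
        assert filter_alignments([low]) == []

    def test_threshold_oracle_on_planted_distribution(self, rng):
        assets = []
        for i in range(214):
            aligned = 100
            matches = int(rng.integers(80, 101))
            qsize = int(rng.integers(100, 220))
            assets.append(make_asset(f"a{i}", matches=matches, aligned=aligned, qsize=qsize))
        kept = filter_alignments(assets)
        brute = [
            a
            for a in assets
            if 100 * a.matches / a.aligned_length >= 93
            and 100 * a.aligned_length / a.query_length >= 55
        ]
        assert kept == brute

    def test_filter_is_idempotent_and_order_free(self, rng):
        assets = [
            make_asset(f"a{i}", matches=int(rng.integers(85, 101)), aligned=100,
                       qsize=int(rng.integers(100, 200)))
            for i in range(30)
        ]
        kept = filter_alignments(assets)
        assert filter_alignments(kept) == kept
        shuffled = list(assets)
        rng.shuffle(shuffled)
        assert sorted(a.asset_id for a in filter_alignments(shuffled)) == sorted(
            a.asset_id for a in kept
        )


class TestExonCount:
    def test_two_block_alignment_is_multi_exon(self):
        assert classify_exon_count(make_asset()) == "multi_exon"

    def test_single_block_is_intronless(self):
        assert classify_exon_count(make_asset(exons=((100, 200),), matches=90,
                                              aligned=100, qsize=100)) == "intronless"


class TestPositionProfile:
    def test_partial_coverage_maps_to_percentile_band(self):
        profile = relative_position_profile([(500, 1000, 2000)])
        assert profile[25:51].sum() == 26
        assert profile.sum() == 26

    def test_full_transcript_covers_every_percentile(self):
        profile = relative_position_profile([(0, 2000, 2000)])
        assert (profile == 1).all()

    def test_outside_transcript_rejected(self):
        with pytest.raises(ValueError):
            relative_position_profile([(500, 2500, 2000)])

    def test_uniform_placement_gives_flat_profile(self, rng):
        from scipy import stats

        length = 10000
        placements = []
        for _ in range(10000):
            start = int(rng.integers(0, length - 50))
            placements.append((start, start + 50, length))
        profile = relative_position_profile(placements)
        # interior percentiles, decimated so adjacent-bin correlation from
        # multi-percentile placements cannot distort the statistic
        interior = profile[2:99:2]
        chi2 = ((interior - interior.mean()) ** 2 / interior.mean()).sum()
        p = stats.chi2.sf(chi2, len(interior) - 1)
        assert p > 0.01
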