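import numpy as np
import pytest

from arti.offtarget import (
    build_index,
    extended_seed_has_match,
    seed_offtarget_score,
    seed_percentiles,
)
from arti.seqcore import NucSeq, SeedSpec, revcomp, subseq
from arti.synthetic import SyntheticSpec, generate_transcriptome

ARTI_6570_GUIDE = "TTCGATAACAATATCATCCGGA"


def _random_records(rng, n, length):
    return [
        NucSeq("".join(rng.choice(list("ACGT"), size=length)), name=f"r{i}")
        for i in range(n)
    ]


class TestBuildIndex:
    def test_overlap_counting(self):
        idx = build_index([NucSeq("ACGTACGT")], k=4)
        assert idx.counts == {"ACGT": 2, "CGTA": 1, "GTAC": 1, "TACG": 1}

    def test_homopolymer_windows(self):
        assert build_index([NucSeq("AAAA")], k=2).counts == {"AA": 3}

    def test_agrees_with_naive_scan(self):
        rng = np.random.default_rng(42)
        recs = _random_records(rng, 50, 200)
        idx = build_index(recs, k=13)
        # sample 13-mers present in the records plus random ones
        probes = [r.bases[i : i + 13] for r in recs[:10] for i in (0, 50, 187)]
        probes += ["".join(rng.choice(list("ACGT"), size=13)) for _ in range(10)]
        for w in probes:
            naive = sum(
                r.bases[i : i + 13] == w
                for r in recs
                for i in range(len(r) - 12)
            )
            assert idx.count(w) == naive

    def test_window_conservation(self):
        rng = np.random.default_rng(1)
        recs = _random_records(rng, 10, 57)
        idx = build_index(recs, k=7)
        assert idx.total_windows == 10 * (57 - 7 + 1)

    def test_n_windows_skipped(self):
        idx = build_index([NucSeq.transcript("ACNGT")], k=2)
        assert idx.counts == {"AC": 1, "GT": 1}

    def test_k_longer_than_records_warns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            idx = build_index([NucSeq("ACGT")], k=10)
        assert idx.counts == {}


class TestExtendedSeedFilter:
    def test_planted_target_strand_match(self):
        # transcript carries revcomp of the guide's extended seed (2-14)
        target_text = revcomp(subseq(ARTI_6570_GUIDE, 2, 14)).bases
        assert target_text == "ATATTGTTATCGA"
        idx = build_index([NucSeq("GGGG" + target_text + "CCCC")], k=13)
        assert extended_seed_has_match(ARTI_6570_GUIDE, idx) is True

    def test_empty_index_never_matches(self):
        with pytest.warns(UserWarning):
            idx = build_index([NucSeq("ACGT")], k=13)
        assert extended_seed_has_match(ARTI_6570_GUIDE, idx) is False

    def test_guide_strand_text_needs_both_orientations(self):
        guide_text = subseq(ARTI_6570_GUIDE, 2, 14).bases
        idx = build_index([NucSeq("GG" + guide_text + "CC")], k=13)
        assert extended_seed_has_match(ARTI_6570_GUIDE, idx) is False
        assert (
            extended_seed_has_match(ARTI_6570_GUIDE, idx, both_orientations=True)
            is True
        )

    def test_k_mismatch_rejected(self):
        idx = build_index([NucSeq("ACGTACGTACGT")], k=7)
        with pytest.raises(ValueError, match="k=7"):
            extended_seed_has_match(ARTI_6570_GUIDE, idx)

    def test_monotone_under_added_records(self):
        rng = np.random.default_rng(3)
        recs = _random_records(rng, 20, 100)
        more = recs + _random_records(rng, 20, 100)
        idx_small = build_index(recs, k=13)
        idx_big = build_index(more, k=13)
        for r in recs[:5]:
            probe = NucSeq("T" + revcomp(r.bases[:13]).bases + "ATCCGGAT")
            if extended_seed_has_match(probe, idx_small):
                assert extended_seed_has_match(probe, idx_big)

    def test_flags_exactly_the_planted_guides(self, golden_entries):
        # plant target sites for three of the six entries; naive-scan oracle
        planted = ["ARTi.6570", "ARTi.6634", "ARTi.6786"]
        motifs = tuple(
            (revcomp(subseq(revcomp(golden_entries[n][0]), 2, 14)).bases, 1, (i,))
            for i, n in enumerate(planted)
        )
        spec = SyntheticSpec(
            rng_seed=11, n_records=6, record_length=300, planted_motifs=motifs
        )
        recs, manifest = generate_transcriptome(spec)
        idx = build_index(recs, k=13)
        text = "".join(r.bases for r in recs)
        for name, (site, _) in golden_entries.items():
            guide = revcomp(site)
            flagged = extended_seed_has_match(guide, idx)
            naive = revcomp(subseq(guide, 2, 14)).bases in text or any(
                revcomp(subseq(guide, 2, 14)).bases in r.bases for r in recs
            )
            assert flagged == naive
            if name in planted:
                assert flagged


class TestSeedOfftargetScore:
    def test_planted_complement_sites(self):
        # 3 planted seed-complement sites for seed TCGATAA
        utrs = [
            NucSeq("AAAA" + "TTATCGA" + "CCCC"),
            NucSeq("TTATCGA" + "GG" + "TTATCGA"),
        ]
        idx = build_index(utrs, k=7)
        sc = seed_offtarget_score("TCGATAA", idx)
        assert sc.complement_hits == 3
        assert sc.normalized_score == pytest.approx(1.5)

    def test_empty_index_scores_zero(self):
        with pytest.warns(UserWarning):
            idx = build_index([NucSeq("ACG")], k=7)
        assert seed_offtarget_score("TCGATAA", idx).complement_hits == 0

    def test_doubling_records_scales_hits_not_normalized(self):
        rng = np.random.default_rng(5)
        utrs = _random_records(rng, 30, 150)
        idx1 = build_index(utrs, k=7)
        idx2 = build_index(utrs + utrs, k=7)
        for seed in ("TCGATAA", "ACGTACG", "CCCCCCC"):
            s1 = seed_offtarget_score(seed, idx1)
            s2 = seed_offtarget_score(seed, idx2)
            assert s2.complement_hits == 2 * s1.complement_hits
            assert abs(s2.normalized_score - s1.normalized_score) < 1e-12

    def test_accepts_full_guide(self):
        utrs = [NucSeq("AAAATTATCGACCCC")]
        idx = build_index(utrs, k=7)
        assert seed_offtarget_score(ARTI_6570_GUIDE, idx).seed.bases == "TCGATAA"


class TestSeedPercentiles:
    def test_mean_rank_formula(self):
        # hit counts 0, 1, 2, 3 -> percentiles 100 * (rank - 0.5) / 4
        seeds = ["AAAAAAA", "CAAAAAA", "GCAAAAA", "TGCAAAA"]
        utrs = [
            NucSeq("TTTTTTG"),                    # 1x revcomp(CAAAAAA)
            NucSeq("TTTTTGC" + "G" + "TTTTTGC"),  # 2x revcomp(GCAAAAA)
            NucSeq("TTTTGCA" * 3),                # 3x revcomp(TGCAAAA)
        ]
        idx = build_index(utrs, k=7)
        df = seed_percentiles(seeds, idx).set_index("seed")
        assert list(df["complement_hits"]) == [0, 1, 2, 3]
        assert list(df["percentile"]) == [12.5, 37.5, 62.5, 87.5]

    def test_total_tie_gives_50(self):
        with pytest.warns(UserWarning):
            idx = build_index([NucSeq("ACG")], k=7)
        df = seed_percentiles(["AAAAAAA", "CCCCCCC", "GGGGGGG"], idx)
        assert (df["percentile"] == 50.0).all()

    def test_planted_clean_seed_lands_in_top_percent(self):
        # every universe seed gets >= 1 planted complement site; the clean
        # seed's complement is kept out of the UTR set entirely
        rng = np.random.default_rng(9)
        universe = sorted(
            {"".join(rng.choice(list("ACGT"), size=7)) for _ in range(1200)}
        )[:999]
        clean = "GCGCGCG"
        universe = [s for s in universe if s != clean]
        # AAA spacers keep junction windows from forming revcomp(clean),
        # which contains no A
        utrs = []
        for i in range(0, len(universe), 20):
            block = "AAA".join(revcomp(s).bases for s in universe[i : i + 20])
            utrs.append(NucSeq(block, name=f"utr{i}"))
        assert all(revcomp(clean).bases not in r.bases for r in utrs)
        idx = build_index(utrs, k=7)
        df = seed_percentiles(universe + [clean], idx).set_index("seed")
        assert df.loc[clean, "complement_hits"] == 0
        assert (df.drop(clean)["complement_hits"] >= 1).all()
        assert df.loc[clean, "percentile"] <= 1.0
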