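"""K80 distances, .align parsing, divergence landscapes, TE-size correlation."""
import math

import numpy as np
import pandas as pd
import pytest

from relict.te_landscape import (
    K2PResult,
    SaturationError,
    TECopyRecord,
    attach_k2p,
    build_landscape,
    classify_family,
    correlate_te_size,
    k2p,
    parse_align,
    parse_te_tsv,
    write_te_tsv,
)


def _oracle_k2p(a, b):
    """Count-then-formula oracle: explicit per-column loop."""
    purines = {"A", "G"}
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in purines) == (y in purines):
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


class TestK2P:
    def test_identical_sequences(self):
        r = k2p("ACGTACGT", "ACGTACGT")
        assert (r.P, r.Q, r.d) == (0.0, 0.0, 0.0)

    def test_closed_form_example(self):
        # 100 sites, 10 transitions, 5 transversions: P=0.1, Q=0.05
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        r = k2p(a, b)
        assert (r.P, r.Q) == (0.1, 0.05)
        assert round(r.d, 4) == 0.1702

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            k2p("AAAA", "GGGG")

    def test_no_comparable_columns(self):
        with pytest.raises(ValueError, match="comparable"):
            k2p("----", "ACGT")

    def test_gap_columns_skipped_pairwise(self):
        r = k2p("ACGT-A", "ACGTTG")
        assert r.n_sites == 5

    def test_matches_count_oracle_on_random_pairs(self, rng):
        """Closed form equals the brute-force oracle to 1e-12 on 1,000 pairs."""
        bases = np.array(list("ACGT"))
        max_delta = 0.0
        for _ in range(1000):
            n = int(rng.integers(50, 300))
            a = bases[rng.integers(4, size=n)]
            b = a.copy()
            m = int(rng.integers(0, max(n // 5, 1)))
            idx = rng.choice(n, size=m, replace=False)
            b[idx] = bases[rng.integers(4, size=m)]
            sa, sb = "".join(a), "".join(b)
            try:
                d = k2p(sa, sb).d
            except SaturationError:
                continue
            max_delta = max(max_delta, abs(d - _oracle_k2p(sa, sb)))
            assert k2p(sb, sa).d == d  # symmetry
        assert max_delta < 1e-12

    def test_monotone_in_transitions_at_fixed_transversions(self):
        base = "A" * 200
        prev = -1.0
        for ts in range(0, 60, 10):
            b = "G" * ts + "C" * 10 + "A" * (190 - ts)
            d = k2p(base, b).d
            assert d > prev
            prev = d


class TestClassifyFamily:
    @pytest.mark.parametrize(
        "family, expected",
        [
            ("rnd-1_family-12#LINE/L2", "LINE"),
            ("rnd-3_family-7#SINE/tRNA-Deu", "SINE"),
            ("fam#LTR/Gypsy", "LTR"),
            ("fam#DNA/TcMar", "DNA"),
            ("fam#RC/Helitron", "RC"),
            ("fam#Simple_repeat", "Other"),
            ("fam#rRNA", "Other"),
            ("fam#Mystery", "Unknown"),
            ("bare_name", "Unknown"),
        ],
    )
    def test_mapping(self, family, expected):
        assert classify_family(family) == expected


class TestParseAlign:
    def _records(self, te_consensus, rng, targets=(0.0, 0.1, 0.3)):
        from relict.synthetic_data import TECopySpec, TEFamily, TESimSpec, gen_te_copies
        fam = TEFamily("rnd-1_family-12", "LINE", te_consensus)
        spec = TESimSpec(
            families=[fam],
            copies=[TECopySpec("rnd-1_family-12", t, 500) for t in targets],
            seed=9,
        )
        return gen_te_copies(spec, {"ctg001": 100_000}, rng)[0]

    def test_three_blocks_three_records(self, tmp_path, te_consensus, rng):
        from relict.synthetic_data import write_te_align
        records = self._records(te_consensus, rng)
        path = tmp_path / "x.align"
        write_te_align(records, path)
        parsed, n_skipped = parse_align(path)
        assert len(parsed) == 3 and n_skipped == 0
        assert all(r.te_class == "LINE" for r in parsed)
        # coordinates and sequences round-trip exactly
        for orig, new in zip(records, parsed):
            assert (new.contig, new.start, new.end) == (orig.contig, orig.start, orig.end)
            assert new.copy_seq == orig.copy_seq and new.cons_seq == orig.cons_seq

    def test_truncated_final_block_skipped_with_count(self, tmp_path, te_consensus, rng):
        from relict.synthetic_data import write_te_align
        records = self._records(te_consensus, rng)
        path = tmp_path / "x.align"
        write_te_align(records, path)
        lines = path.read_text().splitlines(keepends=True)
        headers = [i for i, l in enumerate(lines) if l.startswith("1000 ")]
        assert len(headers) == 3
        # keep the final header plus only its first (query) sequence line
        path.write_text("".join(lines[: headers[2] + 2]))
        parsed, n_skipped = parse_align(path)
        assert len(parsed) == 2 and n_skipped == 1

    def test_tsv_fallback_round_trip(self, tmp_path, te_consensus, rng):
        records = self._records(te_consensus, rng)
        path = tmp_path / "copies.tsv"
        write_te_tsv(records, path)
        parsed, n_skipped = parse_te_tsv(path)
        assert n_skipped == 0
        assert [r.copy_id for r in parsed] == [r.copy_id for r in records]
        assert parsed[1].copy_seq == records[1].copy_seq


def _record(te_class, d, bp, copy_id="c1"):
    rec = TECopyRecord(
        copy_id=copy_id, family=f"f#{te_class}" if te_class != "Unknown" else "f#?",
        te_class=te_class, contig="ctg", start=0, end=bp,
    )
    if d is not None:
        rec.k2p_result = K2PResult(P=d / 2, Q=d / 2, n_sites=bp, d=d)
    return rec


class TestBuildLandscape:
    def test_low_divergence_copy_lands_in_first_bin(self):
        table, _ = build_landscape([_record("LINE", 0.004, 200)], 1_000_000)
        row = table.iloc[0]
        assert (row.bin_low, row.bin_high, row.bp) == (0.0, 0.01, 200)

    def test_te_fraction(self):
        recs = [_record("LINE", 0.01, 100), _record("DNA", 0.02, 50)]
        _, summary = build_landscape(recs, 1_000)
        assert summary["te_fraction"] == pytest.approx(0.15)

    def test_conservation_over_random_records(self, rng):
        classes = ["LINE", "SINE", "LTR", "DNA", "RC", "Unknown", "Other"]
        recs = []
        for i in range(300):
            cls = classes[int(rng.integers(len(classes)))]
            d = float(rng.uniform(0, 0.7)) if rng.random() > 0.1 else None
            recs.append(_record(cls, d, int(rng.integers(50, 2000)), f"c{i}"))
        table, summary = build_landscape(recs, 10_000_000)
        total = sum(r.aligned_copy_bp for r in recs)
        binned = int(table["bp"].sum())
        assert binned + summary["overflow_bp"] + summary["unscorable_bp"] \
            + summary["other_bp"] == total

    def test_overflow_and_unscorable_buckets(self):
        recs = [_record("LINE", 0.6, 100), _record("LINE", None, 50)]
        table, summary = build_landscape(recs, 1_000)
        assert table.empty
        assert summary["overflow_bp"] == 100 and summary["unscorable_bp"] == 50

    def test_invalid_assembly_size(self):
        with pytest.raises(ValueError):
            build_landscape([], 0)


class TestCorrelateTESize:
    def _data(self):
        return pd.DataFrame(
            {"species": list("ABCD"),
             "assembly_size": [244.0, 406.0, 594.0, 1392.0],
             "te_bp": [36.6, 60.9, 89.1, 208.8]}
        )

    def test_proportional_gives_r_one(self):
        out = correlate_te_size(self._data())
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_star_tree_pgls_equals_ols(self):
        data = self._data()
        data["te_bp"] = [30.0, 70.0, 80.0, 210.0]
        tree = "(A:1,B:1,C:1,D:1);"
        out = correlate_te_size(data, tree=tree)
        slope_ols = np.polyfit(data["assembly_size"], data["te_bp"], 1)[0]
        assert out["pgls_slope"] == pytest.approx(slope_ols)
        assert out["pgls_r"] == pytest.approx(out["pearson_r"], abs=1e-9)

    def test_permutation_invariance(self):
        data = self._data()
        tree = "((A:1,B:1):1,(C:1,D:1):1);"
        out1 = correlate_te_size(data, tree=tree)
        out2 = correlate_te_size(data.iloc[[2, 0, 3, 1]].reset_index(drop=True), tree=tree)
        assert out1["pearson_r"] == pytest.approx(out2["pearson_r"])
        assert out1["pgls_slope"] == pytest.approx(out2["pgls_slope"])
        assert out1["pgls_r"] == pytest.approx(out2["pgls_r"])

    def test_missing_tip_is_error(self):
        with pytest.raises(ValueError, match="absent"):
            correlate_te_size(self._data(), tree="(A:1,B:1,C:1);")

    def test_too_few_species(self):
        with pytest.raises(ValueError):
            correlate_te_size(self._data().iloc[:2])
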