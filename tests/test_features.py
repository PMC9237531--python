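"""Window resolution, charge profiling, helix breakers, topology, PTMs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ripscan as rs
from ripscan.features import resolve_window


def make_ann(tffd, tmd, topology="NA", **kw):
    return rs.DomainAnnotation(
        protein_id="P1", tffd=tffd,
        tmds=[rs.TMDSpan(start=tmd[0], end=tmd[1], topology=topology)], **kw)


class TestResolveWindow:
    def test_tffd_side_flank_left_of_tmd(self, table1_by_id):
        # bZIP28: TFFD 192-237 (N-terminal of the TMD 321-344)
        w = resolve_window(table1_by_id["bZIP28"], "flank_tffd_side", k=20)
        assert w.span == (301, 320)

    def test_tffd_side_flank_right_of_tmd(self, table1_by_id):
        # AIL6: TFFD 389-440 C-terminal of the TMD 301-321
        w = resolve_window(table1_by_id["AIL6"], "flank_tffd_side", k=20)
        assert w.span == (322, 341)

    def test_clipping_at_both_termini(self):
        ann = make_ann((1, 3), (5, 25))
        w = resolve_window(ann, "tmd_plus_flank", k=10, length=30)
        assert w.span == (1, 30)

    def test_overlap_class_flank_is_empty(self):
        ann = make_ann((50, 100), (60, 80))
        w = resolve_window(ann, "flank_tffd_side", k=20, length=200)
        assert w.is_empty and len(w) == 0

    def test_flank_abuts_but_excludes_tmd(self):
        ann = make_ann((10, 60), (101, 120))
        w = resolve_window(ann, "flank_tffd_side", k=5, length=200)
        assert w.span == (96, 100)

    def test_idempotent_and_clip_safe(self):
        ann = make_ann((2, 4), (6, 26))
        for label, k in [("tmd", None), ("tmd_plus_flank", 7),
                         ("flank_tffd_side", 7)]:
            w1 = resolve_window(ann, label, k=k, length=28)
            w2 = resolve_window(ann, label, k=k, length=28)
            assert w1 == w2
            if not w1.is_empty:
                assert w1.start >= 1 and w1.end <= 28

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(k1=st.integers(1, 20), k2=st.integers(1, 20),
           tmd_start=st.integers(30, 150), tffd_left=st.booleans())
    def test_flank_nesting(self, k1, k2, tmd_start, tffd_left):
        if k1 > k2:
            k1, k2 = k2, k1
        tmd = (tmd_start, tmd_start + 20)
        tffd = (5, 25) if tffd_left and tmd_start > 26 else (tmd[1] + 5, tmd[1] + 60)
        if not (tffd[1] < tmd[0] or tffd[0] > tmd[1]):
            return
        ann = make_ann(tffd, tmd)
        w1 = resolve_window(ann, "flank_tffd_side", k=k1, length=300)
        w2 = resolve_window(ann, "flank_tffd_side", k=k2, length=300)
        if not w1.is_empty:
            assert w2.start <= w1.start and w1.end <= w2.end


class TestChargeProfile:
    def test_counts_in_toy_tmd(self):
        seq = "A" * 10 + "LLKLLARLL" + "A" * 10
        rec = rs.ProteinRecord(id="P1", sequence=seq)
        with pytest.warns(UserWarning):  # 9-residue TMD is unusually short
            ann = make_ann((1, 5), (11, 19))
        prof = rs.charge_profile(rec, ann, ks=(5,))
        assert (prof.k_tmd, prof.r_tmd) == (1, 1)

    def test_degenerate_window_counts_zero(self):
        seq = "K" * 200
        rec = rs.ProteinRecord(id="P1", sequence=seq)
        ann = make_ann((50, 100), (60, 80))  # overlap: no TFFD-side flank
        prof = rs.charge_profile(rec, ann)
        for k in (5, 10, 15, 20):
            assert prof.flank(k) == (0, 0, 0)

    def test_matches_indicator_oracle(self, rng):
        for _ in range(20):
            L = int(rng.integers(120, 300))
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
            rec = rs.ProteinRecord(id="P1", sequence=seq)
            ts = int(rng.integers(40, L - 30))
            ann = make_ann((5, 30), (ts, min(L, ts + 20)))
            prof = rs.charge_profile(rec, ann)
            for k in (5, 10, 15, 20):
                w = resolve_window(ann, "flank_tffd_side", k=k, length=L)
                kc = sum(seq[i - 1] == "K" for i in range(w.start, w.end + 1))
                rc = sum(seq[i - 1] == "R" for i in range(w.start, w.end + 1))
                ln = 0 if w.is_empty else w.end - w.start + 1
                assert prof.flank(k) == (kc, rc, ln)


class TestHelixBreakers:
    def test_ga_found_in_tmd(self, toy_mbtf):
        rec, ann = toy_mbtf
        hits = rs.find_helix_breakers(rec, ann)
        names = {h.motif_name for h in hits}
        assert "GA" in names
        ga = [h for h in hits if h.motif_name == "GA" and h.orientation == "forward"]
        assert ga[0].span == (87, 88)

    def test_pure_leucine_tmd_clean(self):
        seq = "A" * 20 + "L" * 21 + "A" * 20
        rec = rs.ProteinRecord(id="P1", sequence=seq)
        ann = make_ann((1, 10), (21, 41))
        assert rs.find_helix_breakers(rec, ann) == []

    def test_pxxp_hit(self):
        seq = "A" * 20 + "LLLLPLLPLLLLLLLLLLLLL" + "A" * 20
        rec = rs.ProteinRecord(id="P1", sequence=seq)
        ann = make_ann((1, 10), (21, 41))
        hits = rs.find_helix_breakers(rec, ann)
        pxxp = [h for h in hits if h.motif_name == "PxxP"]
        assert pxxp and pxxp[0].span == (25, 28)

    def test_hits_outside_tmd_ignored(self):
        seq = "NPNP" + "A" * 16 + "L" * 21 + "A" * 20
        rec = rs.ProteinRecord(id="P1", sequence=seq)
        ann = make_ann((5, 15), (21, 41))
        assert rs.find_helix_breakers(rec, ann) == []


class TestTopology:
    @pytest.mark.parametrize("pid,expect", [
        ("bZIP60", ("C", "II", "cytosolic")),
        ("NTL1", ("C", "I", "luminal")),
        ("bZIP28", ("C", "I", "luminal")),
        ("AIL6", ("N", "I", "cytosolic")),
        ("LOL1", ("N", "II", "luminal")),
    ])
    def test_fixture_rows(self, table1_by_id, pid, expect):
        tc = rs.classify_topology(table1_by_id[pid])
        assert (tc.position_class, tc.topology, tc.tffd_side) == expect

    def test_overlap_side_na(self):
        tc = rs.classify_topology(make_ann((50, 100), (60, 80), topology="I"))
        assert (tc.position_class, tc.tffd_side) == ("overlap", "NA")

    def test_missing_topology_side_na(self):
        tc = rs.classify_topology(make_ann((10, 60), (100, 120)))
        assert (tc.position_class, tc.topology, tc.tffd_side) == ("C", "NA", "NA")

    def test_partition_is_total(self, rng):
        import warnings as _w
        classes = set()
        for _ in range(200):
            a, b = sorted(rng.integers(1, 200, size=2))
            c, d = sorted(rng.integers(1, 200, size=2))
            if b == a:
                b += 1
            if d == c:
                d += 12
            try:
                with _w.catch_warnings():
                    _w.simplefilter("ignore")  # arbitrary TMD lengths here
                    ann = make_ann((a, b), (c, d))
            except Exception:
                continue
            classes.add(rs.classify_topology(ann).position_class)
        assert classes <= {"N", "C", "overlap"}

    def test_all_ntls_cytosolic_except_ntl1(self, table1):
        sides = {a.protein_id: rs.classify_topology(a).tffd_side
                 for a in table1 if a.protein_id.startswith("NTL")}
        assert sides.pop("NTL1") == "luminal"
        assert sides and all(v == "cytosolic" for v in sides.values())


class TestPTMPositioning:
    def test_between_and_inside(self):
        ann = make_ann((10, 100), (200, 220))
        ann.ptms.extend([
            rs.PTMRecord(kind="phosphorylation", position=150),
            rs.PTMRecord(kind="phosphorylation", position=50),
            rs.PTMRecord(kind="phosphorylation", position=100),  # boundary
            rs.PTMRecord(kind="phosphorylation", position=200),  # boundary
        ])
        between = rs.ptm_between_tffd_and_tmd(ann)
        assert [p.position for p in between] == [150]

    def test_overlap_class_empty(self):
        ann = make_ann((50, 100), (60, 80))
        ann.ptms.append(rs.PTMRecord(kind="phosphorylation", position=55))
        assert rs.ptm_between_tffd_and_tmd(ann) == []

    def test_unpositioned_between_flag_included(self):
        ann = make_ann((10, 100), (200, 220))
        ann.ptms.append(rs.PTMRecord(kind="phosphorylation",
                                     between_domains=True))
        assert len(rs.ptm_between_tffd_and_tmd(ann)) == 1

    def test_proteolytic_nterm_proximity_rule(self):
        ann = make_ann((10, 100), (200, 220))
        ann.ptms.append(rs.PTMRecord(kind="proteolytic N-terminus",
                                     position=170))
        assert rs.proteolytic_nterm_near_tmd(ann)  # 200-170 = 30 <= 41
        ann2 = make_ann((10, 100), (200, 220))
        ann2.ptms.append(rs.PTMRecord(kind="proteolytic N-terminus",
                                      position=120))
        assert not rs.proteolytic_nterm_near_tmd(ann2)  # 80 > 41
        ann3 = make_ann((10, 100), (200, 220))
        ann3.ptms.append(rs.PTMRecord(kind="proteolytic N-terminus",
                                      position=230))  # wrong side
        assert not rs.proteolytic_nterm_near_tmd(ann3)
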