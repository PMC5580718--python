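"""Anchoring, trio genotyping, transmission phasing and iteration."""

import itertools

import numpy as np
import pytest

from triophaser.io_core import BubbledScaffold, Bubble, parse_bubbled_body, reverse_complement
from triophaser.triophase import (
    MEMBERS,
    TrioPhaseCall,
    build_consensus,
    build_search_index,
    emit_haplotypes,
    extract_anchors,
    fill_gaps,
    genotype_site,
    iterate_phasing,
    match_anchors,
    phase_by_transmission,
    run_phasing,
)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# Anchor extraction


class TestExtractAnchors:
    def test_bubble_at_40_uses_first_40_bases(self, rng):
        bb = random_dna(rng, 100)
        sc = BubbledScaffold("s", bb, [Bubble(40, bb[40], "T" if bb[40] != "T" else "A")])
        (rec,) = extract_anchors(sc).records
        assert rec.anchorable
        assert rec.ufs == bb[:40]
        assert rec.rufs == reverse_complement(bb[:40])

    def test_bubble_at_39_unanchorable(self, rng):
        bb = random_dna(rng, 100)
        sc = BubbledScaffold("s", bb, [Bubble(39, bb[39], "T" if bb[39] != "T" else "A")])
        (rec,) = extract_anchors(sc).records
        assert not rec.anchorable

    def test_n_in_window_unanchorable(self, rng):
        bb = random_dna(rng, 50) + "N" + random_dna(rng, 50)
        sc = BubbledScaffold("s", bb, [Bubble(60, bb[60], "T" if bb[60] != "T" else "A")])
        (rec,) = extract_anchors(sc).records
        assert not rec.anchorable

    def test_rufs_involution(self, rng):
        bb = random_dna(rng, 80)
        sc = BubbledScaffold("s", bb, [Bubble(60, bb[60], "T" if bb[60] != "T" else "A")])
        (rec,) = extract_anchors(sc).records
        assert reverse_complement(rec.rufs) == rec.ufs


# ---------------------------------------------------------------------------
# Matching


def _trio_from_backbones(backbones, bubbles):
    return {
        m: BubbledScaffold(m, bb, bubbles.get(m, []))
        for m, bb in zip(MEMBERS, backbones)
    }


class TestMatchAnchors:
    def test_planted_unique_site_anchored_everywhere(self, rng):
        core = random_dna(rng, 300)
        trio = {}
        for i, m in enumerate(MEMBERS):
            pad = random_dna(rng, 50 + 30 * i)
            bb = pad + core
            pos = len(pad) + 150
            ref = bb[pos]
            trio[m] = BubbledScaffold(m, bb, [Bubble(pos, ref, "T" if ref != "T" else "A")])
        tables = {m: extract_anchors(s, member=m) for m, s in trio.items()}
        sites = match_anchors(tables, trio)
        assert len(sites) == 1
        for i, m in enumerate(MEMBERS):
            assert sites[0].positions[m] == 50 + 30 * i + 150

    def test_duplicated_ufs_discarded(self, rng):
        """A UFS occurring twice in the father yields no anchored site."""
        seg = random_dna(rng, 60)
        father_bb = seg + random_dna(rng, 40) + seg + random_dna(rng, 40)
        pos = len(father_bb) - 1
        other = random_dna(rng, len(father_bb))
        trio = _trio_from_backbones(
            [father_bb, other, other],
            {"father": [Bubble(60, father_bb[60], "T" if father_bb[60] != "T" else "A")]},
        )
        tables = {m: extract_anchors(s, member=m) for m, s in trio.items()}
        sites = match_anchors(tables, trio, use_downstream=False)
        assert sites == []

    def test_ufs_straddling_neighbour_bubble_still_matches(self, rng):
        """Both allele paths are searched, so a het inside the flank is fine."""
        bb = random_dna(rng, 400)
        # neighbour bubble at 180 (inside the 40-bp flank of site 200)
        site, nb = 200, 180
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}
        child = BubbledScaffold(
            "child", bb,
            [Bubble(nb, bb[nb], alt[bb[nb]]), Bubble(site, bb[site], alt[bb[site]])],
        )
        # father carries the *other* allele at the neighbour site, flat
        father_bb = bb[:nb] + alt[bb[nb]] + bb[nb + 1 :]
        father = BubbledScaffold("father", father_bb, [])
        mother = BubbledScaffold("mother", bb, [])
        trio = {"father": father, "mother": mother, "child": child}
        tables = {m: extract_anchors(s, member=m) for m, s in trio.items()}
        sites = match_anchors(tables, trio)
        positions = {tuple(s.positions[m] for m in MEMBERS) for s in sites}
        assert (site, site, site) in positions


# ---------------------------------------------------------------------------
# Genotyping


class TestGenotypeSite:
    def _site(self, trio, pos):
        tables = {m: extract_anchors(s, member=m) for m, s in trio.items()}
        sites = match_anchors(tables, trio)
        (site,) = [s for s in sites if s.positions["child"] == pos]
        return site

    def test_bubble_and_flat_genotypes(self, rng):
        bb = random_dna(rng, 200)
        pos = 100
        a, g = bb[pos], {"A": "G", "C": "A", "G": "C", "T": "A"}[bb[pos]]
        trio = {
            "father": BubbledScaffold("father", bb, [Bubble(pos, a, g)]),
            "mother": BubbledScaffold("mother", bb, []),
            "child": BubbledScaffold("child", bb, [Bubble(pos, a, g)]),
        }
        call = genotype_site(trio, self._site(trio, pos))
        assert sorted(call.genotypes["father"]) == sorted((a, g))
        assert call.genotypes["mother"] == (a, a)
        assert call.status != "excluded"

    def test_exhaustive_read_off_matches_strings(self, rng):
        """Three-site toy trio: genotypes equal direct string inspection."""
        bb = random_dna(rng, 400)
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}
        positions = [100, 200, 300]
        trio = {}
        expected = {}
        for m_i, m in enumerate(MEMBERS):
            bubbles = []
            exp = {}
            for p_i, p in enumerate(positions):
                if (m_i + p_i) % 2 == 0:  # het here
                    bubbles.append(Bubble(p, bb[p], alt[bb[p]]))
                    exp[p] = tuple(sorted((bb[p], alt[bb[p]])))
                else:
                    exp[p] = (bb[p], bb[p])
            trio[m] = BubbledScaffold(m, bb, bubbles)
            expected[m] = exp
        for p in positions:
            call = genotype_site(trio, self._site(trio, p))
            for m in MEMBERS:
                assert tuple(sorted(call.genotypes[m])) == expected[m][p]

    def test_n_lookup_excludes_site(self, rng):
        bb = random_dna(rng, 200)
        pos = 100
        a, g = bb[pos], {"A": "G", "C": "A", "G": "C", "T": "A"}[bb[pos]]
        mother_bb = bb[:pos] + "N" + bb[pos + 1 :]
        trio = {
            "father": BubbledScaffold("father", bb, [Bubble(pos, a, g)]),
            "mother": BubbledScaffold("mother", mother_bb, []),
            "child": BubbledScaffold("child", bb, [Bubble(pos, a, g)]),
        }
        call = genotype_site(trio, self._site(trio, pos))
        assert call.status == "excluded"
        assert call.genotypes["mother"] is None


# ---------------------------------------------------------------------------
# Transmission phasing — exhaustive oracle


def _phase_oracle(father, mother, child):
    """Enumerate parental transmissions; classify the configuration."""
    consistent = set()
    for fi, mi in itertools.product((0, 1), repeat=2):
        if sorted((father[fi], mother[mi])) == sorted(child):
            consistent.add((father[fi], mother[mi]))
    if not consistent:
        return "violation", None
    if len(consistent) == 1:
        return "phased", next(iter(consistent))
    return "unphased", None


def _call(father, mother, child):
    return TrioPhaseCall(
        pos=50,
        positions={m: 50 for m in MEMBERS},
        ref="A",
        alt="G",
        genotypes={"father": father, "mother": mother, "child": child},
        status="unphased",
        phased_samples={m: False for m in MEMBERS},
    )


class TestPhaseByTransmission:
    def test_hom_parents_resolve_child(self):
        call = phase_by_transmission(_call(("A", "A"), ("G", "G"), ("A", "G")))
        assert call.status == "phased"
        assert (call.child_paternal, call.child_maternal) == ("A", "G")

    def test_triple_het_unphased(self):
        call = phase_by_transmission(_call(("A", "G"), ("A", "G"), ("A", "G")))
        assert call.status == "unphased" and call.mendel == "OK"

    def test_violation_detected(self):
        call = phase_by_transmission(_call(("A", "A"), ("A", "A"), ("A", "G")))
        assert call.mendel == "VIOL"

    def test_all_27_configurations_match_enumeration(self):
        """Exhaustive biallelic truth table against the transmission oracle."""
        gts = [("A", "A"), ("A", "G"), ("G", "G")]
        for father, mother, child in itertools.product(gts, repeat=3):
            call = phase_by_transmission(_call(father, mother, child))
            status, assignment = _phase_oracle(father, mother, child)
            if status == "violation":
                assert call.mendel == "VIOL"
            elif status == "phased":
                assert call.status == "phased"
                assert (call.child_paternal, call.child_maternal) == assignment
                assert (call.father_transmitted, call.mother_transmitted) == assignment
            else:
                assert call.status == "unphased" and call.mendel == "OK"


# ---------------------------------------------------------------------------
# Haplotype emission


class TestEmitHaplotypes:
    def _phased_trio(self, rng, ref_allele, alt_allele, pos=100):
        bb = random_dna(rng, 200)
        bb = bb[:pos] + ref_allele + bb[pos + len(ref_allele) :]
        father = BubbledScaffold("father", bb, [Bubble(pos, ref_allele, alt_allele)])
        mother = BubbledScaffold("mother", bb, [])
        child = BubbledScaffold("child", bb, [Bubble(pos, ref_allele, alt_allele)])
        trio = {"father": father, "mother": mother, "child": child}
        call = phase_by_transmission(
            _call(
                (ref_allele, alt_allele),
                (ref_allele, ref_allele),
                (ref_allele, alt_allele),
            )
        )
        call.positions = {m: pos for m in MEMBERS}
        call.pos = pos
        return trio, call

    def test_single_phased_snv_changes_one_position(self, rng):
        trio, call = self._phased_trio(rng, "A", "G")
        hs = emit_haplotypes(trio, [call])
        bb = trio["child"].backbone
        pat, mat = hs.sequences["child_paternal"], hs.sequences["child_maternal"]
        assert sum(a != b for a, b in zip(pat, bb)) + sum(
            a != b for a, b in zip(mat, bb)
        ) == 1  # exactly one haplotype differs at exactly one position

    def test_deletion_shifts_downstream_coordinates(self, rng):
        """A phased 3-bp deletion shifts later coordinates by -3."""
        trio, call = self._phased_trio(rng, "ACTG", "A")
        # father transmitted the deletion allele in this configuration?
        # force it: child paternal = alt (A), i.e. deletion inherited
        call.child_paternal = call.father_transmitted = "A"
        call.child_maternal = call.mother_transmitted = "ACTG"
        hs = emit_haplotypes(trio, [call])
        cmap = hs.coord_maps["child_paternal"]
        assert cmap(100) == 100
        assert cmap(104) == 101  # first base after the bubble shifts by -3
        assert cmap(150) == 147

    def test_unphased_bubble_becomes_n_run(self, rng):
        trio, call = self._phased_trio(rng, "ACTG", "A")
        call.status = "unphased"
        hs = emit_haplotypes(trio, [call])
        assert hs.sequences["child_paternal"][100:104] == "NNNN"

    def test_child_derives_from_parent_at_phased_sites(self, small_outcome):
        """Transmission consistency, asserted post hoc on a simulated trio."""
        hs = small_outcome.hapset
        for call in hs.calls:
            if call.status != "phased":
                continue
            for parent, ckey in (
                ("father", "child_paternal"),
                ("mother", "child_maternal"),
            ):
                allele = (
                    call.child_paternal if parent == "father" else call.child_maternal
                )
                cpos = hs.coord_maps[ckey](call.positions["child"])
                assert hs.sequences[ckey][cpos : cpos + len(allele)] == allele
                tkey = f"{parent}_transmitted"
                ppos = hs.coord_maps[tkey](call.positions[parent])
                assert hs.sequences[tkey][ppos : ppos + len(allele)] == allele


# ---------------------------------------------------------------------------
# Consensus


def _nw_oracle(a, b):
    """Tiny independent Needleman-Wunsch (unit costs) for <=50-bp segments."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1))
    for i in range(n + 1):
        dp[i][0] = i
    for j in range(m + 1):
        dp[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i][j] = min(
                dp[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
                dp[i - 1][j] + 1,
                dp[i][j - 1] + 1,
            )
    return dp[n][m]


class TestBuildConsensus:
    def test_identical_segments_no_disagreement(self, rng):
        seq = random_dna(rng, 500)
        cons, dis = build_consensus(seq, seq, [(100, 100, 1), (300, 300, 1)])
        assert cons == seq and dis == []

    def test_n_run_filled_from_child(self, rng):
        seq = random_dna(rng, 200)
        parent = seq[:50] + "N" * 10 + seq[60:]
        cons, dis = build_consensus(parent, seq, [(100, 100, 1)])
        assert cons == seq and dis == []

    def test_planted_substitution_logged_once(self, rng):
        seq = random_dna(rng, 200)
        child = seq[:70] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[70]] + seq[71:]
        cons, dis = build_consensus(seq, child, [(150, 150, 1)])
        assert cons == child  # mismatch resolved toward the child
        assert dis == [70]
        # cross-check the segment really differs by one edit
        assert _nw_oracle(seq[:50], child[:50]) == 0
        assert _nw_oracle(seq[60:80], child[60:80]) == 1

    def test_structural_disagreement_masked(self, rng):
        parent = random_dna(rng, 40)
        child = random_dna(rng, 200)
        cons, _ = build_consensus(parent, child, [])
        assert cons == "N" * len(child)


# ---------------------------------------------------------------------------
# Gap fill and iteration


class TestIteration:
    def test_fill_gaps_closes_join_n(self, rng):
        donor_bb = random_dna(rng, 300)
        target_bb = donor_bb[:150] + "N" + donor_bb[150:]
        target = BubbledScaffold("t", target_bb, [])
        donor = BubbledScaffold("d", donor_bb, [])
        filled, smap = fill_gaps(target, [donor])
        assert filled.backbone == donor_bb  # join N removed
        assert smap(200) == 199

    def test_fill_gaps_replaces_masked_run(self, rng):
        donor_bb = random_dna(rng, 300)
        target_bb = donor_bb[:150] + "N" * 10 + donor_bb[160:]
        filled, _ = fill_gaps(
            BubbledScaffold("t", target_bb, []), [BubbledScaffold("d", donor_bb, [])]
        )
        assert filled.backbone == donor_bb

    def test_rounds_zero_returns_input(self, small_outcome):
        assert iterate_phasing(small_outcome, rounds=0) is small_outcome

    def test_phased_fraction_nondecreasing(self, small_outcome):
        fr = small_outcome.phased_fraction_per_round
        assert len(fr) == 2
        assert fr[1] >= fr[0] - 1e-12

    def test_gap_crossing_flank_rescued_in_round_two(self, rng):
        """A site whose flank crosses a join N phases only after filling."""
        bb = random_dna(rng, 400)
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}
        pos = 200
        var = Bubble(pos, bb[pos], alt[bb[pos]])
        child_bb = bb[:180] + "N" + bb[180:]  # join inside the child's flank
        child = BubbledScaffold("child", child_bb, [Bubble(pos + 1, bb[pos], alt[bb[pos]])])
        father = BubbledScaffold("father", bb, [var])
        mother = BubbledScaffold("mother", bb, [])
        trio = {"father": father, "mother": mother, "child": child}
        one = run_phasing(trio, rounds=1)
        two = run_phasing(trio, rounds=2)
        phased_one = sum(c.status == "phased" for c in one.calls)
        phased_two = sum(c.status == "phased" for c in two.calls)
        assert phased_one == 0
        assert phased_two == 1


# ---------------------------------------------------------------------------
# Search index details


class TestSearchIndex:
    def test_plain_kmers_anchor_next_coordinate(self, rng):
        bb = random_dna(rng, 120)
        idx = build_search_index(BubbledScaffold("s", bb, []), k=40)
        assert idx[bb[0:40]] in (40, None) or idx[bb[0:40]] == 40
        assert idx[bb[50:90]] == 90

    def test_alt_path_kmer_present(self, rng):
        bb = random_dna(rng, 200)
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}
        b = Bubble(100, bb[100], alt[bb[100]])
        idx = build_search_index(BubbledScaffold("s", bb, [b]), k=40)
        alt_kmer = bb[70:100] + b.right + bb[101:110]
        assert len(alt_kmer) == 40
        assert idx[alt_kmer] == 110
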