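"""ce_call: CE calling rules, recurrence, duration, NG86 counting."""

import itertools
import random

import pytest

from ceseek.ce_call import (DatedSpeciesTree, call_ce, codon_syn_sites,
                            estimate_duration, ng86_identity, recurrence_filter)
from ceseek.clan_scan import ParalogClanEvent
from ceseek.synteny import SyntenyType


def _clan(sp, support, genes=None):
    genes = genes or {f"{sp}_1", f"{sp}_2"}
    return ParalogClanEvent("fam", sp, frozenset(genes), support)


def _types(species, per_species_genes=("_1", "_2")):
    """Two synteny types, each spanning all given species."""
    return [
        SyntenyType(f"T{k + 1}", "fam",
                    {sp: f"{sp}{suffix}" for sp in species},
                    {(f"{a}{suffix}", f"{b}{suffix}"): 5
                     for a, b in itertools.combinations(sorted(species), 2)})
        for k, suffix in enumerate(per_species_genes)
    ]


SPECIES = [f"s{i}" for i in range(6)]


class TestCallCe:
    def test_supported_clan_with_two_types_called(self):
        events, diags = call_ce([_clan("s0", 95)], _types(SPECIES))
        assert len(events) == 1 and diags == []
        assert events[0].syntype_ids == ("T1", "T2")

    def test_support_below_threshold_rejected(self):
        events, diags = call_ce([_clan("s0", 69)], _types(SPECIES))
        assert events == [] and diags[0].reason == "low_support"

    def test_boundary_support_70_accepted(self):
        events, _ = call_ce([_clan("s0", 70)], _types(SPECIES))
        assert len(events) == 1

    def test_missing_support_rejected(self):
        events, diags = call_ce([_clan("s0", None)], _types(SPECIES))
        assert events == [] and diags[0].reason == "low_support"

    def test_paralog_without_synteny_rejected(self):
        types = _types(SPECIES)[:1]  # only T1 (the "_1" copies)
        events, diags = call_ce([_clan("s0", 90)], types)
        assert events == [] and diags[0].reason == "no_synteny"

    def test_single_shared_type_rejected(self):
        # both paralogs inside one type spanning many species
        t = SyntenyType("T1", "fam", {f"v{sp}": f"{sp}_1" for sp in SPECIES}, {})
        t.members.update({sp: f"{sp}_2" for sp in SPECIES})
        events, diags = call_ce([_clan("s0", 90)], [t])
        assert events == [] and diags[0].reason == "same_type"

    def test_reasons_partition_clan_species(self):
        clans = [_clan("s0", 95), _clan("s1", 50), _clan("s2", 80)]
        types = _types(["s0", "s2", "s3"])
        events, diags = call_ce(clans, types)
        called = {e.species_id for e in events}
        diagnosed = {d.species_id for d in diags}
        assert called | diagnosed == {"s0", "s1", "s2"}
        assert called & diagnosed == set()


class TestRecurrence:
    @staticmethod
    def _events(n):
        events, _ = call_ce([_clan(f"s{i}", 90) for i in range(n)],
                            _types([f"s{i}" for i in range(max(n, 2))]))
        return events

    def test_five_species_recurrent(self):
        (report,) = recurrence_filter(self._events(5))
        assert report.recurrent and report.n_species == 5

    def test_four_species_not_recurrent(self):
        (report,) = recurrence_filter(self._events(4))
        assert not report.recurrent

    def test_no_events_no_report(self):
        assert recurrence_filter([]) == []


NEWICK = "((a:10,b:10):439,(c:200,d:200):249):0;"


class TestDuration:
    @pytest.fixture()
    def dated(self):
        return DatedSpeciesTree.from_newick(NEWICK, is_path=False)

    @staticmethod
    def _report(species):
        from ceseek.ce_call import CEGeneReport
        return CEGeneReport("fam", sorted(species), recurrent=len(species) >= 5)

    def test_mrca_age(self, dated):
        assert estimate_duration(self._report({"a", "c"}), dated) == pytest.approx(449)

    def test_all_leaves_root_age(self, dated):
        assert estimate_duration(self._report({"a", "b", "c", "d"}),
                                 dated) == pytest.approx(449)

    def test_sister_pair_ignores_negatives(self, dated):
        assert estimate_duration(self._report({"a", "b"}), dated) == pytest.approx(10)

    def test_missing_species_listed(self, dated):
        with pytest.raises(ValueError, match="zz"):
            estimate_duration(self._report({"a", "zz"}), dated)

    def test_monotone_in_species_set(self, dated):
        smaller = estimate_duration(self._report({"a", "b"}), dated)
        larger = estimate_duration(self._report({"a", "b", "c"}), dated)
        assert larger >= smaller

    def test_non_ultrametric_tree_rejected(self):
        with pytest.raises(Exception):
            DatedSpeciesTree.from_newick("((a:10,b:7):5,c:15):0;", is_path=False)


# ---------------------------------------------------------------------------
# NG86

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
          if c not in _STOPS]


def oracle_ng86(ca: str, cb: str):
    """Independent per-codon oracle using Biopython translation."""
    from Bio.Seq import Seq

    def aa(codon):
        return str(Seq(codon).translate())

    def syn_sites(codon):
        s = 0.0
        for pos, base in itertools.product(range(3), "ACGT"):
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if mut not in _STOPS and aa(mut) == aa(codon):
                s += 1 / 3
        return s

    diff = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, steps, ok = ca, [], True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in _STOPS and nxt != cb:
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        for order in itertools.permutations(diff):
            cur, steps = ca, []
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                steps.append((cur, nxt))
                cur = nxt
            paths.append(steps)
    sd = sum(aa(x) == aa(y) for p in paths for x, y in p) / len(paths)
    nd = sum(aa(x) != aa(y) for p in paths for x, y in p) / len(paths)
    return (syn_sites(ca) + syn_sites(cb)) / 2, sd, nd


class TestNg86:
    def test_identical_sequences_zero(self):
        res = ng86_identity("TTTGGA", "TTTGGA")
        assert res.sd == res.nd == 0 and res.pS == res.pN == 0

    def test_synonymous_third_position(self):
        res = ng86_identity("TTT", "TTC")  # Phe -> Phe
        assert res.sd == 1 and res.nd == 0

    def test_nonsynonymous_third_position(self):
        res = ng86_identity("TTT", "TTA")  # Phe -> Leu
        assert res.sd == 0 and res.nd == 1

    def test_phe_codon_syn_sites(self):
        assert codon_syn_sites("TTT") == pytest.approx(1 / 3)

    def test_sites_sum_to_length(self):
        res = ng86_identity("TTTGGAACC", "TTCGGTACC")
        assert res.S + res.N == pytest.approx(9)

    @pytest.mark.parametrize("bad,err", [
        (("TTTG", "TTTG"), "divisible"),
        (("TTT", "TTTGGA"), "length"),
        (("TAA", "TTT"), "stop"),
    ])
    def test_invalid_input_rejected(self, bad, err):
        with pytest.raises(ValueError, match=err):
            ng86_identity(*bad)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle_on_random_pairs(self, seed):
        rng = random.Random(seed)
        for _ in range(30):
            ca, cb = rng.choice(_SENSE), rng.choice(_SENSE)
            res = ng86_identity(ca, cb)
            S, sd, nd = oracle_ng86(ca, cb)
            assert res.S == pytest.approx(S)
            assert res.sd == pytest.approx(sd)
            assert res.nd == pytest.approx(nd)

    def test_proportions_bounded(self):
        rng = random.Random(3)
        a = "".join(rng.choice(_SENSE) for _ in range(30))
        b = "".join(rng.choice(_SENSE) for _ in range(30))
        res = ng86_identity(a, b)
        assert 0 <= res.pS <= 1 and 0 <= res.pN <= 1
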