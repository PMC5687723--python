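import pytest

from dcapskit.alphabet import reverse_complement
from dcapskit.enzymes import filter_enzymes
from dcapskit.fixtures import generate_fixtures
from dcapskit.pipeline import RunConfig, run_screen
from dcapskit.primers import PrimerOptions
from dcapskit.reports import to_json
from dcapskit.scan import predict_fragments
from dcapskit.screen import (
    DEFAULT_PROFILE,
    EditEvent,
    EditProfile,
    MultipleProtospacerHits,
    ProtospacerNotFound,
    last_shared_base_all,
    locate_cut_site,
    screen_assays,
    simulate_edits,
)
from oracle import loss_oracle

from dcapskit.fixtures import random_sequence

#: real Cas9 target from the AHK3 genotyping experiment (locus AT1G27320)
AHK3_PROTOSPACER = "GGTTGAGATCAAGATAGACA"


class TestCutSite:
    def test_forward_minus_three_rule(self, rng):
        left = random_sequence(rng, 30)
        wt = left + AHK3_PROTOSPACER + "TGG" + random_sequence(rng, 27)
        bond, strand = locate_cut_site(wt, AHK3_PROTOSPACER)
        assert (bond, strand) == (30 + 17, "+")
        # the bond separates ...GATAG from ACA<PAM>
        assert wt[bond - 5 : bond] == "GATAG" and wt[bond : bond + 3] == "ACA"

    def test_reverse_strand_match(self, rng):
        left = random_sequence(rng, 25)
        wt = left + reverse_complement(AHK3_PROTOSPACER) + random_sequence(rng, 25)
        bond, strand = locate_cut_site(wt, AHK3_PROTOSPACER)
        assert strand == "-"
        assert bond == 25 + 3  # -3 position measured from the PAM side

    def test_absent_and_ambiguous(self, rng):
        wt = random_sequence(rng, 80)
        with pytest.raises(ProtospacerNotFound):
            locate_cut_site(wt, AHK3_PROTOSPACER)
        doubled = AHK3_PROTOSPACER + "TTTT" + AHK3_PROTOSPACER
        with pytest.raises(MultipleProtospacerHits):
            locate_cut_site(doubled, AHK3_PROTOSPACER)


class TestEditSimulation:
    def test_default_profile_five_variants(self):
        variants = simulate_edits("AAAATTTT", 4)
        assert variants == [
            "AAAAATTTT",  # +A
            "AAAACTTTT",  # +C
            "AAAAGTTTT",  # +G
            "AAAATTTTT",  # +T
            "AAATTTT",  # deletion of the base 5' of the cut
        ]

    def test_empty_and_custom_profiles(self):
        assert simulate_edits("AAAATTTT", 4, EditProfile(events=())) == []
        two_bp = EditProfile(events=(EditEvent("deletion", 2, 1.0),))
        assert simulate_edits("AAAATTTT", 4, two_bp) == ["AATTTT"]

    def test_profile_weights_validated(self):
        with pytest.raises(ValueError):
            EditProfile(events=(EditEvent("insertion", "A", 0.7),))


class TestLastSharedBase:
    def test_identical_variant(self):
        assert last_shared_base_all("ACGTACGT", ["ACGTACGT"]) == 7

    def test_homopolymer_runs_back(self):
        wt = "ACGTAAAAGT"
        variants = simulate_edits(wt, 6)
        # the insertion-C variant diverges at index 6; the A-run absorbs
        # insertions of A, so the anchor retreats 5' of the naive cut
        assert last_shared_base_all(wt, variants) == 5

    def test_brute_force_prefix_agreement(self, rng):
        for _ in range(50):
            wt = random_sequence(rng, 60)
            cut = int(rng.integers(21, 40))
            variants = simulate_edits(wt, cut)
            got = last_shared_base_all(wt, variants)
            longest = max(
                l
                for l in range(min(len(wt), min(map(len, variants))) + 1)
                if all(v[:l] == wt[:l] for v in variants)
            )
            assert got == longest - 1


def _nlaiii_locus():
    """Synthetic locus where NlaIII (CATG) spans the cut as CAT^G: the +G
    insertion regenerates the site, every other event destroys it."""
    left = "AAGGTTCCAAGGTTCCAAGGTTCCAAGGTT"  # 30 nt, CATG-free
    ps = "GGACCTTGGACCTTCATGAC"  # CATG at protospacer 14..17, cut CAT^G
    right = "TGG" + "AACCTTGGAACCTTGGAACCTTGGAACCTT"
    wt = left + ps + right
    assert wt.count("CATG") == 1 and reverse_complement(wt).count("CATG") == 1
    return wt, ps


class TestLossMachinery:
    def test_partial_loss_and_inclusive_threshold(self, catalogue):
        wt, ps = _nlaiii_locus()
        nla = filter_enzymes(catalogue, include=["NlaIII"])
        strict = screen_assays(wt, ps, nla, loss_threshold=0.0)
        assert strict == []
        tolerant = screen_assays(wt, ps, nla, loss_threshold=0.2)
        assert tolerant and all(r.loss_fraction == 0.2 for r in tolerant)
        for r in tolerant:
            calls = dict(r.per_event_calls)
            assert calls["+G"] == "cut"
            assert all(v == "uncut" for k, v in calls.items() if k != "+G")

    def test_threshold_monotonicity(self, sub20, rng):
        for _ in range(5):
            fx = generate_fixtures(int(rng.integers(2**31)), 1, "crispr_locus")[0]
            wt = fx["records"][0][1]
            ps = fx["truth"]["protospacer"]
            prev: set = set()
            for thr in (0.0, 0.2, 0.6, 1.0):
                cur = {
                    (r.assay.enzyme.name, r.assay.motif_start, r.assay.orientation)
                    for r in screen_assays(wt, ps, sub20, loss_threshold=thr)
                }
                assert prev <= cur
                prev = cur

    def test_loss_matches_digest_oracle(self, sub20):
        """Emitted loss fractions equal an independent per-event digest."""
        weights = [e.weight for e in DEFAULT_PROFILE.events]
        for fx in generate_fixtures(29, 20, "crispr_locus"):
            wt = fx["records"][0][1]
            ps = fx["truth"]["protospacer"]
            bond = fx["truth"]["cut_bond"]
            fwd_variants = simulate_edits(wt, bond)
            for r in screen_assays(wt, ps, sub20, loss_threshold=1.0):
                if r.assay.orientation == "forward":
                    oriented_wt, variants = wt, fwd_variants
                else:
                    oriented_wt = reverse_complement(wt)
                    variants = [reverse_complement(v) for v in fwd_variants]
                expected = loss_oracle(
                    oriented_wt,
                    list(zip(weights, variants)),
                    r.assay.enzyme,
                    r.assay.motif_start,
                    dict(r.assay.patches),
                    150,
                )
                assert r.loss_fraction == pytest.approx(expected)
                assert r.loss_fraction in (0.0, 0.2, 0.4, 0.6, 0.8)


class TestDeterminism:
    def test_reports_are_byte_identical(self, sub20):
        wt, ps = _nlaiii_locus()
        cfg = RunConfig(loss_threshold=0.4)
        a = to_json(run_screen(wt, ps, cfg, sub20)[0])
        b = to_json(run_screen(wt, ps, cfg, sub20)[0])
        assert a == b


class TestAhk3StyleEndToEnd:
    """Synthetic stand-in for the published AHK3 screening assay.

    The real genomic flanks are not bundled; this locus embeds the real
    protospacer with constructed flanks so that a BsaBI site
    (GATNN^NNATC) spans the Cas9 cut and needs exactly one primer
    mismatch — the geometry the published assay had: a 90-bp amplicon
    whose wild-type allele digests into 36 + 54 bp while 1-bp insertion
    alleles stay uncut.
    """

    LEFT = "CTTGGACC" * 5  # 40 nt, free of GAT/ATC
    RIGHT = "TGG" + ("CCTTGGAA" * 4 + "C")  # PAM + 33 nt
    WT = LEFT + AHK3_PROTOSPACER + RIGHT

    def test_screen_finds_single_mismatch_bsabi_assay(self, catalogue):
        bsabi = filter_enzymes(catalogue, include=["BsaBI"])
        results = screen_assays(
            self.WT,
            AHK3_PROTOSPACER,
            bsabi,
            loss_threshold=0.0,
            primer_options=PrimerOptions(
                max_mismatch=1, mode="fixed_length", length=36
            ),
        )
        assert results, "expected a BsaBI screening assay"
        assert {r.assay.orientation for r in results} == {"reverse_complement"}
        r = results[0]
        assert r.primer.mismatch_count == 1
        assert r.loss_fraction == 0.0
        assert all(call == "uncut" for _, call in r.per_event_calls)

    def test_wildtype_digest_and_insertion_alleles(self, catalogue):
        bsabi = filter_enzymes(catalogue, include=["BsaBI"])[0]
        results = screen_assays(
            self.WT,
            AHK3_PROTOSPACER,
            [bsabi],
            loss_threshold=0.0,
            primer_options=PrimerOptions(
                max_mismatch=1, mode="fixed_length", length=36
            ),
        )
        r = results[0]
        amp = r.primer.amplicon(1, 90)
        assert len(amp) == 90
        assert predict_fragments(amp, bsabi) == [36, 54]
        # the diagnostic cut falls exactly at the Cas9 cut bond
        bond, _ = locate_cut_site(self.WT, AHK3_PROTOSPACER)
        rc_wt = reverse_complement(self.WT)
        anchor = r.primer.anchor_3prime
        assert anchor == len(self.WT) - bond - 1
        # every simulated 1-bp edit leaves the amplicon uncut
        for variant in simulate_edits(self.WT, bond):
            rc_var = reverse_complement(variant)
            edited_amp = (r.primer.sequence + rc_var[anchor + 1 :])[:90]
            assert predict_fragments(edited_amp, bsabi) == [len(edited_amp)]
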