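"""Annotation propagation and the LoF/GoF candidate cascades."""
import random

import pytest

from pts1scan.filters import (
    GeneContext,
    LocalizationAnnotation,
    gof_cascade,
    lof_cascade,
    propagate_annotations,
)
from pts1scan.pipeline import run_on_bundle
from pts1scan.scoring import NOT_TARGETED, TARGETED, TWILIGHT, PTS1Result
from pts1scan.simulate import DECOY_FAILQC, GOF, LOF
from pts1scan.variants import TripeptideChange, VariantRecord


def _ann(pid, *keywords, specific=False):
    return LocalizationAnnotation.make(pid, keywords, specific)


def _change(gene, tid, wt, mt, pos=100, passing=True, codon_index=2):
    v = VariantRecord("1", pos, "A", "G", pass_exome=passing, rsid=f"rs{pos}")
    return TripeptideChange(tid, gene, v, wt, mt, codon_index, "missense")


def _result(wt_cat, mt_cat):
    return PTS1Result(0.0, 1.0, wt_cat, mt_cat, 1.0)


class TestPropagateAnnotations:
    def test_canonical_annotation_extends_to_isoforms(self):
        anns = {"C1": _ann("C1", "Cytoplasm")}
        completed, missing = propagate_annotations(anns, {"G": ["C1", "I1", "I2"]})
        assert completed["I1"].keywords == frozenset({"cytoplasm"})
        assert completed["I2"].keywords == frozenset({"cytoplasm"})
        assert missing == []

    def test_isoform_specific_annotation_wins(self):
        anns = {
            "C1": _ann("C1", "Cytoplasm"),
            "I1": _ann("I1", "Nucleus", specific=True),
        }
        completed, _ = propagate_annotations(anns, {"G": ["C1", "I1"]})
        assert completed["I1"].keywords == frozenset({"nucleus"})

    def test_empty_table_leaves_everything_unannotated(self):
        completed, missing = propagate_annotations({}, {"G": ["C1", "I1"]})
        assert completed == {} and missing == ["G"]


class TestLofCascade:
    CTX = {"EHH": GeneContext("EHH", has_omim_disease=True, protein_length=723)}

    def _run(self, change, annotations, contexts=None, genes=("EHH",)):
        return lof_cascade([change], annotations, contexts or self.CTX, genes)

    def test_peroxisome_only_omim_pass_variant_retained(self):
        """The SKL>GKL pattern: exclusively peroxisomal, disease
        linked, quality-passing, consensus lost."""
        c = _change("EHH", "T_EHH", "SKL", "GKL")
        out = self._run(c, {"T_EHH": _ann("T_EHH", "Peroxisome")})
        assert out.retained == [c]
        assert all(n_out <= n_in for n_in, n_out in out.stage_counts.values())

    def test_dual_localization_excluded_at_localization_stage(self):
        c = _change("EHH", "T_EHH", "SKL", "GKL")
        out = self._run(c, {"T_EHH": _ann("T_EHH", "Peroxisome", "Cytoplasm")})
        assert out.retained == []
        assert out.exclusion_log == [(c, "peroxisome_only_localization")]

    def test_manual_include_overrides_second_compartment_keyword(self):
        """A gene whose mutant form carries a mitochondrial keyword can
        be whitelisted explicitly instead of hard-coding exceptions."""
        ctx = {"AGX": GeneContext("AGX", has_omim_disease=True, manual_include=True)}
        c = _change("AGX", "T_AGX", "SKL", "GKL")
        out = lof_cascade(
            [c], {"T_AGX": _ann("T_AGX", "Peroxisome", "Mitochondrion")}, ctx, ["AGX"]
        )
        assert out.retained == [c]

    def test_mutant_still_canonical_excluded_at_consensus_stage(self):
        c = _change("EHH", "T_EHH", "SKL", "AKL")
        out = self._run(c, {"T_EHH": _ann("T_EHH", "Peroxisome")})
        assert out.exclusion_log == [(c, "consensus_lost")]

    def test_failed_quality_excluded_at_quality_stage(self):
        c = _change("EHH", "T_EHH", "SKL", "GKL", passing=False)
        out = self._run(c, {"T_EHH": _ann("T_EHH", "Peroxisome")})
        assert out.exclusion_log == [(c, "quality_pass")]

    def test_missing_annotation_excluded_as_unannotated(self):
        c = _change("EHH", "T_EHH", "SKL", "GKL")
        out = self._run(c, {})
        assert out.exclusion_log == [(c, "peroxisome_only_localization")]

    def test_token_matching_does_not_confuse_compound_keywords(self):
        """'Cytoplasmic vesicle' is a different token than 'Cytoplasm'
        and must not trigger the dual-localization exclusion."""
        c = _change("EHH", "T_EHH", "SKL", "GKL")
        out = self._run(c, {"T_EHH": _ann("T_EHH", "Peroxisome", "Cytoplasmic vesicle")})
        assert out.retained == [c]


class TestGofCascade:
    def _ctx(self, gene="PPP", tid="T_PPP", length=873, tmd=False):
        return {
            gene: GeneContext(
                gene, protein_length=length, has_tmd=tmd,
                transcript_lengths={tid: length},
            )
        }

    def test_cytosolic_category_gain_retained(self):
        """The SNP>SNL pattern: cytosolic, Not targeted to Targeted,
        873 residues, no transmembrane domain."""
        c = _change("PPP", "T_PPP", "SNP", "SNL")
        results = {("T_PPP",) + c.variant.key: _result(NOT_TARGETED, TARGETED)}
        out = gof_cascade([c], {"T_PPP": _ann("T_PPP", "Cytoplasm")}, self._ctx(), results)
        assert out.retained == [c]

    def test_twilight_to_targeted_passes_category_stage(self):
        c = _change("GLT", "T_GLT", "YKV", "CKV")
        results = {("T_GLT",) + c.variant.key: _result(TWILIGHT, TARGETED)}
        ctx = self._ctx("GLT", "T_GLT", length=209)
        out = gof_cascade([c], {"T_GLT": _ann("T_GLT", "Cytoplasm")}, ctx, results)
        assert out.retained == [c]

    def test_long_protein_excluded_at_size_stage(self):
        c = _change("BIG", "T_BIG", "SNP", "SNL")
        results = {("T_BIG",) + c.variant.key: _result(NOT_TARGETED, TARGETED)}
        ctx = self._ctx("BIG", "T_BIG", length=1200)
        out = gof_cascade([c], {"T_BIG": _ann("T_BIG", "Cytoplasm")}, ctx, results)
        assert out.exclusion_log == [(c, "length_and_no_tmd")]

    def test_only_longest_transcript_kept_per_gene(self):
        c_long = _change("G", "T_LONG", "SNP", "SNL")
        c_short = _change("G", "T_SHORT", "SNP", "SNL")
        ctx = {
            "G": GeneContext(
                "G", protein_length=900,
                transcript_lengths={"T_LONG": 900, "T_SHORT": 400},
            )
        }
        anns = {t: _ann(t, "Cytoplasm") for t in ("T_LONG", "T_SHORT")}
        results = {
            (t,) + c_long.variant.key: _result(NOT_TARGETED, TARGETED)
            for t in ("T_LONG", "T_SHORT")
        }
        out = gof_cascade([c_long, c_short], anns, ctx, results)
        assert [c.transcript_id for c in out.retained] == ["T_LONG"]
        assert (c_short, "longest_transcript") in out.exclusion_log

    def test_longest_transcript_tie_broken_lexicographically(self):
        c_a = _change("G", "T_A", "SNP", "SNL")
        c_b = _change("G", "T_B", "SNP", "SNL")
        ctx = {"G": GeneContext("G", protein_length=500,
                                transcript_lengths={"T_A": 500, "T_B": 500})}
        anns = {t: _ann(t, "Cytoplasm") for t in ("T_A", "T_B")}
        results = {
            (t,) + c_a.variant.key: _result(NOT_TARGETED, TARGETED)
            for t in ("T_A", "T_B")
        }
        out = gof_cascade([c_a, c_b], anns, ctx, results)
        assert [c.transcript_id for c in out.retained] == ["T_A"]


class TestCascadeProperties:
    def _inputs(self, n=30, seed=5):
        rng = random.Random(seed)
        changes, anns, ctxs, results = [], {}, {}, {}
        genes = []
        for i in range(n):
            gene, tid = f"G{i}", f"T{i}"
            wt = rng.choice(["SKL", "AKL", "SNP", "TKL", "DDD"])
            mt = rng.choice(["GKL", "AEL", "SNL", "SKL", "DDE"])
            c = _change(gene, tid, wt, mt, pos=1000 + i, passing=rng.random() < 0.8)
            changes.append(c)
            kw = rng.sample(["Peroxisome", "Cytoplasm", "Nucleus", "Secreted"], k=rng.randint(1, 2))
            anns[tid] = _ann(tid, *kw)
            ctxs[gene] = GeneContext(
                gene, has_omim_disease=rng.random() < 0.5,
                protein_length=rng.randint(100, 1500),
                transcript_lengths={tid: rng.randint(100, 1500)},
            )
            results[(tid,) + c.variant.key] = _result(
                rng.choice([NOT_TARGETED, TWILIGHT, TARGETED]),
                rng.choice([NOT_TARGETED, TWILIGHT, TARGETED]),
            )
            if rng.random() < 0.5:
                genes.append(gene)
        return changes, anns, ctxs, results, genes

    def test_conservation_and_telescoping(self):
        changes, anns, ctxs, results, genes = self._inputs()
        for out in (
            lof_cascade(changes, anns, ctxs, genes),
            gof_cascade(changes, anns, ctxs, results),
        ):
            assert len(out.retained) + len(out.exclusion_log) == len(changes)
            counts = list(out.stage_counts.values())
            for (i1, o1), (i2, _) in zip(counts, counts[1:]):
                assert o1 == i2
            assert counts[0][0] == len(changes)

    def test_retained_set_invariant_under_shuffling(self):
        changes, anns, ctxs, results, genes = self._inputs()
        shuffled = list(changes)
        random.Random(1).shuffle(shuffled)
        a = lof_cascade(changes, anns, ctxs, genes)
        b = lof_cascade(shuffled, anns, ctxs, genes)
        assert a.retained == b.retained and a.stage_counts == b.stage_counts
        a = gof_cascade(changes, anns, ctxs, results)
        b = gof_cascade(shuffled, anns, ctxs, results)
        assert a.retained == b.retained and a.stage_counts == b.stage_counts

    def test_adding_exclusion_keyword_never_increases_retention(self):
        """Growing any annotation's keyword set can only shrink (or
        keep) the retained sets of both cascades."""
        changes, anns, ctxs, results, genes = self._inputs(seed=9)
        base_lof = len(lof_cascade(changes, anns, ctxs, genes).retained)
        base_gof = len(gof_cascade(changes, anns, ctxs, results).retained)
        for extra in ("Nucleus", "Mitochondrion", "Endosome"):
            bigger = {
                tid: LocalizationAnnotation.make(tid, set(a.keywords) | {extra})
                for tid, a in anns.items()
            }
            assert len(lof_cascade(changes, bigger, ctxs, genes).retained) <= base_lof
            assert len(gof_cascade(changes, bigger, ctxs, results).retained) <= base_gof


def test_planted_truth_recovered_exactly_on_synthetic_data(default_bundle, matrix):
    """End to end on the generated bundle: the LoF and GoF cascades
    retain exactly the planted events and every decoy is excluded at
    the intended stage."""
    res = run_on_bundle(default_bundle, matrix)
    truth = {t.variant_key: t for t in default_bundle.truth}
    lof_expected = {k for k, t in truth.items() if t.planted_class == LOF}
    gof_expected = {k for k, t in truth.items() if t.planted_class == GOF}
    assert {c.variant.key for c in res.lof.retained} == lof_expected
    assert {c.variant.key for c in res.gof.retained} == gof_expected
    # fail-QC decoys reach the cascade but die at the quality stage
    qc_keys = {k for k, t in truth.items() if t.planted_class == DECOY_FAILQC}
    lof_excluded = {c.variant.key: stage for c, stage in res.lof.exclusion_log}
    for k in qc_keys:
        assert lof_excluded[k] == "quality_pass"
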