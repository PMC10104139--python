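"""Motif models, reference-anchored evaluation and collection scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcacheam.anchor_align import AlignedRow, Alignment, SequenceRecord, map_positions
from dcacheam.motif import (
    CLASS_MEMBERS,
    ResidueClass,
    builtin_motif,
    compare_motifs,
    detect_charged_pair_insertion,
    evaluate_motif,
    load_motif_config,
    scan_collection,
)
from dcacheam.synthetic import CANONICAL_AM, SequenceSimSpec, generate_sequences


def pair_alignment(template, query_residues, query_id="q"):
    return Alignment(
        [
            AlignedRow(template.id, template.residues),
            AlignedRow(query_id, query_residues),
        ],
        template.id,
    )


def mapped(template, query_residues, motif, query_id="q"):
    aln = pair_alignment(template, query_residues, query_id)
    return map_positions(aln, motif.reference_positions)


def substitute(residues: str, pos: int, res: str) -> str:
    return residues[: pos - 1] + res + residues[pos:]


# ---------------------------------------------------------------------------
# Built-in motif tables


def test_amine_motif_has_ten_positions_nine_required(am_motif):
    assert len(am_motif.positions) == 10
    assert len(am_motif.required_positions) == 9
    optional = [p for p in am_motif.positions if not p.required]
    assert [p.reference_position for p in optional] == [206]


def test_amine_motif_positions_strictly_increasing(am_motif):
    pos = am_motif.reference_positions
    assert pos == sorted(pos) and len(set(pos)) == len(pos)
    assert pos[0] == 103 and pos[-1] == 235


def test_amino_acid_motif_has_positive_at_start_amine_does_not(am_motif, aa_motif):
    aa_positive = [
        p for p in aa_motif.required_positions if p.residue_class.name == "POSITIVE"
    ]
    assert [p.reference_position for p in aa_positive] == [126]
    am_in_range = [
        p
        for p in am_motif.required_positions
        if 120 <= p.reference_position <= 130 and p.residue_class.name == "POSITIVE"
    ]
    assert am_in_range == []


def test_unknown_motif_name_lists_available():
    with pytest.raises(ValueError, match="AM, AA"):
        builtin_motif("ZZ")


def test_residue_class_invariants():
    with pytest.raises(ValueError):
        ResidueClass("EXACT(DD)", frozenset("DE"))
    with pytest.raises(ValueError):
        ResidueClass("BAD", frozenset())
    assert ResidueClass.named("AROMATIC").members == frozenset("FWY")
    assert not ResidueClass.named("POSITIVE").matches("H")  # H excluded
    assert not ResidueClass.named("ANY").matches("X")  # unknown residue never matches


# ---------------------------------------------------------------------------
# Evaluation


def test_template_is_full_match(template, am_motif):
    pm = mapped(template, template.residues, am_motif)
    res = evaluate_motif("q", pm, am_motif)
    assert res.label == "full_match" and res.mismatch_count == 0


def test_single_substitution_gives_near_miss(template, am_motif):
    variant = substitute(template.residues, 155, "A")
    res = evaluate_motif("q", mapped(template, variant, am_motif), am_motif)
    assert res.label == "near_miss"
    assert res.mismatch_count == 1
    assert res.failing_positions == [155]


def test_two_substitutions_give_no_match(template, am_motif):
    variant = substitute(substitute(template.residues, 155, "A"), 235, "G")
    res = evaluate_motif("q", mapped(template, variant, am_motif), am_motif)
    assert res.label == "no_match" and res.mismatch_count == 2


def test_gap_at_required_position_counts_as_mismatch(template, am_motif):
    gapped = substitute(template.residues, 235, "-")
    aln = Alignment(
        [AlignedRow(template.id, template.residues), AlignedRow("q", gapped)],
        template.id,
    )
    pm = map_positions(aln, am_motif.reference_positions)
    res = evaluate_motif("q", pm, am_motif)
    assert res.mismatch_count == 1 and res.failing_positions == [235]


def test_optional_position_never_counts(template, am_motif):
    variant = substitute(template.residues, 206, "A")  # optional aromatic site
    res = evaluate_motif("q", mapped(template, variant, am_motif), am_motif)
    assert res.label == "full_match" and res.mismatch_count == 0


def test_uncovered_motif_position_is_an_error(template, am_motif):
    pm = mapped(template, template.residues, am_motif)
    partial = type(pm)(pm.alignment, [e for e in pm.entries if e[0] != 173])
    with pytest.raises(ValueError, match="173"):
        evaluate_motif("q", partial, am_motif)


def test_evaluation_ignores_non_motif_residues(template, am_motif):
    rng = np.random.default_rng(7)
    residues = list(template.residues)
    motif_pos = set(am_motif.reference_positions)
    for i in range(len(residues)):
        if (i + 1) not in motif_pos:
            residues[i] = str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY")))
    res = evaluate_motif("q", mapped(template, "".join(residues), am_motif), am_motif)
    assert res.label == "full_match"


@given(st.integers(0, 8), st.integers(0, 19))
@settings(max_examples=40)
def test_mismatch_count_monotone_under_substitution(template, am_motif, which, res_idx):
    """Substituting any required motif position never decreases mismatches."""
    pos = [p.reference_position for p in am_motif.required_positions][which]
    res = "ACDEFGHIKLMNPQRSTVWY"[res_idx]
    base = evaluate_motif("q", mapped(template, template.residues, am_motif), am_motif)
    variant = substitute(template.residues, pos, res)
    after = evaluate_motif("q", mapped(template, variant, am_motif), am_motif)
    assert after.mismatch_count >= base.mismatch_count


def test_random_match_probability_is_class_frequency_product(am_motif):
    expected = 1.0
    for p in am_motif.required_positions:
        expected *= len(p.residue_class.members) / 20.0
    assert am_motif.random_match_probability() == pytest.approx(expected)
    assert expected < 1e-3  # random sequences essentially never match


# ---------------------------------------------------------------------------
# Charged-pair insertion


def test_charged_pair_detected_on_template(template):
    pm = mapped(template, template.residues, builtin_motif("AM"))
    assert detect_charged_pair_insertion("q", pm) is True


def test_charged_pair_lost_on_r103a(template, am_motif):
    variant = substitute(template.residues, 103, "A")
    pm = mapped(template, variant, am_motif)
    assert detect_charged_pair_insertion("q", pm) is False


def test_charged_pair_accepts_class_equivalents(template, am_motif):
    variant = substitute(substitute(template.residues, 103, "K"), 133, "E")
    pm = mapped(template, variant, am_motif)
    assert detect_charged_pair_insertion("q", pm) is True


# ---------------------------------------------------------------------------
# Collection scanning


@pytest.fixture(scope="module")
def small_benchmark():
    spec = SequenceSimSpec(
        n_am=20, n_aa=10, n_near_miss=10, n_random=20, mutation_rate=0.05, seed=11
    )
    return generate_sequences(spec)


def test_scan_recovers_truth_labels(small_benchmark, am_motif, aa_motif):
    template, records, truth = small_benchmark
    table = scan_collection(records, [am_motif, aa_motif], reference=template)
    am_labels = {
        r.query_id: r.label for r in table.results if r.motif_name == "AM"
    }
    for _, row in truth.iterrows():
        expected = {
            "AM": "full_match",
            "AM_1mm": "near_miss",
            "AA": "no_match",
            "random": "no_match",
        }[row["class"]]
        assert am_labels[row["id"]] == expected, row["id"]


def test_near_miss_failing_position_matches_truth(small_benchmark, am_motif):
    template, records, truth = small_benchmark
    table = scan_collection(records, [am_motif], reference=template)
    by_id = {r.query_id: r for r in table.results}
    for _, row in truth[truth["class"] == "AM_1mm"].iterrows():
        assert by_id[row["id"]].failing_positions == [int(row["mismatch_position"])]


def test_scan_is_deterministic(tmp_path, small_benchmark, am_motif):
    template, records, _ = small_benchmark
    paths = []
    for i in range(2):
        table = scan_collection(records, [am_motif], reference=template)
        p = tmp_path / f"scan{i}.tsv"
        table.write_tsv(p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_labels_partition_every_sequence(small_benchmark, am_motif, aa_motif):
    template, records, _ = small_benchmark
    table = scan_collection(records, [am_motif, aa_motif], reference=template)
    summary = table.summary()
    for motif in ("AM", "AA"):
        assert sum(summary[motif].values()) == len(records)


def test_empty_collection_rejected(template, am_motif):
    with pytest.raises(ValueError, match="empty"):
        scan_collection([], [am_motif], reference=template)


def test_scan_without_motifs_rejected(template):
    with pytest.raises(ValueError, match="motif"):
        scan_collection([template], [], reference=template)


# ---------------------------------------------------------------------------
# AM vs AA comparison


def test_am_implanted_sequences_are_am_only(small_benchmark, am_motif, aa_motif):
    template, records, truth = small_benchmark
    table = scan_collection(records, [am_motif, aa_motif], reference=template)
    cmp = compare_motifs(table, "AM", "AA")
    am_ids = set(truth[truth["class"] == "AM"]["id"])
    for qid in am_ids:
        assert cmp["per_sequence"][qid] == "AM-only"
    aa_ids = set(truth[truth["class"] == "AA"]["id"])
    for qid in aa_ids:
        assert cmp["per_sequence"][qid] == "AA-only"


def test_sequence_failing_unshared_positions_is_neither(template, am_motif, aa_motif):
    # default AM and AA tables constrain disjoint anchor positions, so a
    # sequence broken at every position of both motifs satisfies only the
    # (empty) shared set and is labelled neither
    residues = template.residues
    for m in (am_motif, aa_motif):
        for p in m.required_positions:
            bad = sorted(set("ACDEFGHIKLMNPQRSTVWY") - p.residue_class.members)[0]
            residues = substitute(residues, p.reference_position, bad)
    table = scan_collection(
        [SequenceRecord("q", residues)], [am_motif, aa_motif], reference=template
    )
    cmp = compare_motifs(table, "AM", "AA")
    assert cmp["per_sequence"]["q"] == "neither"
    assert cmp["shared_positions"] == []


def test_single_motif_table_rejected(small_benchmark, am_motif):
    template, records, _ = small_benchmark
    table = scan_collection(records[:5], [am_motif], reference=template)
    with pytest.raises(ValueError, match="both motifs"):
        compare_motifs(table, "AM", "AA")


# ---------------------------------------------------------------------------
# Motif config files


def test_motif_config_tsv_round_trip(tmp_path, am_motif):
    p = tmp_path / "motif.tsv"
    lines = ["reference_position\tclass\tmembers\tweight\tlabel"]
    for mp in am_motif.positions:
        members = "".join(sorted(mp.residue_class.members))
        lines.append(
            f"{mp.reference_position}\t{mp.residue_class.name}\t{members}\t"
            f"{mp.weight}\t{mp.label}"
        )
    p.write_text("\n".join(lines) + "\n")
    loaded = load_motif_config(p, name="AM")
    assert [q.reference_position for q in loaded.positions] == am_motif.reference_positions
    for got, want in zip(loaded.positions, am_motif.positions):
        assert got.residue_class.members == want.residue_class.members
        assert got.weight == want.weight


def test_motif_config_yaml_overrides_members(tmp_path):
    p = tmp_path / "motif.yaml"
    p.write_text(
        "name: custom\nreference_id: myref\npositions:\n"
        "  - {reference_position: 5, class: AROMATIC, members: 'FW', weight: required}\n"
        "  - {reference_position: 9, class: 'EXACT(D)', weight: required}\n"
    )
    m = load_motif_config(p)
    assert m.name == "custom"
    assert m.positions[0].residue_class.members == frozenset("FW")
    assert m.positions[1].residue_class.members == frozenset("D")
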