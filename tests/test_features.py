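"""The 94-feature encoding: state codes, flanks, MFE profile, loop distance."""

import numpy as np
import pytest

from maturescan import SynthSpec, align_arms, build_window, extract, generate
from maturescan.features import (
    MAX_WINDOW_COLUMNS,
    N_DISTANCE_FEATURES,
    N_DOWNSTREAM_SLOTS,
    N_FEATURES,
    N_LOWER_STEM_SLOTS,
    N_MFE_FEATURES,
    N_WINDOW_SLOTS,
    column_states,
    duplex_energy,
    encode_flanks,
    encode_window_states,
    loop_distance,
    mfe_profile,
)
from maturescan.hairpin import AlignmentColumn
from maturescan.windowing import enumerate_candidates


def test_layout_accounting():
    """60 window + 18 lower-stem + 6 downstream + 9 MFE + 1 distance = 94."""
    assert (
        N_WINDOW_SLOTS
        + N_LOWER_STEM_SLOTS
        + N_DOWNSTREAM_SLOTS
        + N_MFE_FEATURES
        + N_DISTANCE_FEATURES
        == N_FEATURES
        == 94
    )


class TestStateCodes:
    @pytest.mark.parametrize(
        "col, expected",
        [
            (AlignmentColumn("G", "C", 0, 9, True), (3, 2)),   # Gp, Cp
            (AlignmentColumn("A", "-", 0, None, False), (5, 9)),  # A-, gap
            (AlignmentColumn("-", "U", None, 9, False), (9, 8)),  # gap, U-
            (AlignmentColumn("A", "U", 0, 9, True), (1, 4)),   # Ap, Up
            (AlignmentColumn("C", "A", 0, 9, False), (6, 5)),  # mismatch
        ],
    )
    def test_code_table(self, col, expected):
        assert column_states(col) == expected

    def test_perfect_window_has_48_states_then_padding(self, perfect_alignment):
        w = build_window(perfect_alignment, 10, arm="5p")
        codes = encode_window_states(w, perfect_alignment)
        assert codes.shape == (60,)
        assert np.count_nonzero(codes) == 48
        assert (codes[48:] == 0).all()
        assert set(codes[:48]) <= {1, 2, 3, 4}

    def test_virtual_slots_encode_missing(self, flush_alignment):
        w = build_window(flush_alignment, 0, arm="5p", mature_len=4)
        codes = encode_window_states(w, flush_alignment)
        assert (codes[:4] == 0).all() and codes[4] != 0

    def test_state_histogram_conserves_nucleotides(self, default_dataset):
        for rec in default_dataset.records[:25]:
            al = align_arms(rec)
            for w in enumerate_candidates(al, rec.id).candidates:
                codes = encode_window_states(w, al)
                n_cols = min(
                    w.n_virtual + (w.col_span[1] - w.col_span[0]),
                    MAX_WINDOW_COLUMNS,
                )
                kept = w.columns(al)[
                    : max(0, n_cols - w.n_virtual)
                ]
                expected_nt = sum(
                    (c.five != "-") + (c.three != "-") for c in kept
                )
                assert ((codes >= 1) & (codes <= 8)).sum() == expected_nt


class TestFlanks:
    def test_window_flush_with_precursor_start(self, flush_alignment):
        w = build_window(flush_alignment, 0, arm="5p", mature_len=4)
        lower, down = encode_flanks(w, flush_alignment)
        assert (lower == 0).all()

    def test_downstream_pads_beyond_stem(self, flush_alignment):
        # 6-bp stem, window ends at the loop-adjacent column
        w = build_window(flush_alignment, 2, arm="5p", mature_len=4)
        _, down = encode_flanks(w, flush_alignment)
        assert (down == 0).all()

    def test_mid_stem_flanks_all_paired(self, perfect_alignment):
        w = build_window(perfect_alignment, 12, arm="5p", mature_len=20)
        lower, down = encode_flanks(w, perfect_alignment)
        assert down.shape == (6,)
        assert set(down) <= {1.0, 2.0, 3.0, 4.0}
        # 9 columns upstream may run into the 2-column 3' overhang
        assert set(lower) <= {0.0, 1.0, 2.0, 3.0, 4.0, 8.0, 9.0, 5.0, 6.0, 7.0}
        assert (lower[:12] >= 1).all() and (lower[:12] <= 4).all()


class TestMfe:
    def test_complementary_segments_bind(self):
        assert duplex_energy("GGGG", "CCCC") < 0

    def test_unpairable_segments_have_zero_energy(self):
        assert duplex_energy("AAAA", "AAAA") == 0.0

    def test_empty_segment_is_zero(self):
        assert duplex_energy("", "CCCC") == 0.0

    def test_difference_identities(self, default_dataset):
        for rec in default_dataset.records[:10]:
            al = align_arms(rec)
            for w in enumerate_candidates(al, rec.id).candidates[:5]:
                p = mfe_profile(w, al)
                assert p.mfe6 == p.mfe2 - p.mfe1
                assert p.mfe7 == p.mfe3 - p.mfe2
                assert p.mfe8 == p.mfe4 - p.mfe3
                assert p.mfe9 == p.mfe5 - p.mfe1

    def test_energy_non_increasing_with_added_pairs(self):
        energies = [duplex_energy("G" * k, "C" * k) for k in range(2, 9)]
        assert all(b <= a for a, b in zip(energies, energies[1:]))


class TestLoopDistance:
    def test_counts_nucleotides_to_loop(self, perfect_alignment):
        w = build_window(perfect_alignment, 10, arm="5p")
        # window starts 2 nt basal of the mature start
        first = w.first_five_index(perfect_alignment)
        assert loop_distance(w, perfect_alignment) == (
            perfect_alignment.loop_span[0] - first
        )

    def test_window_abutting_loop(self, flush_alignment):
        w = build_window(flush_alignment, 2, arm="5p", mature_len=4)
        # window = columns 0..5, all six 5'-arm stem nucleotides
        assert loop_distance(w, flush_alignment) == 6

    def test_invariant_under_basal_extension(self):
        spec = dict(
            n_precursors=1, arm_len=(30, 30), loop_len=(6, 6),
            bulge_rate=0, mismatch_rate=0,
            plant_site_determinants=False, seed=3,
        )
        d_short = generate(SynthSpec(**spec, basal_overhang=(0, 0)))
        d_long = generate(SynthSpec(**spec, basal_overhang=(6, 6)))
        dists = []
        for ds, shift in ((d_short, 0), (d_long, 6)):
            al = align_arms(ds.records[0])
            w = build_window(al, 4 + shift, arm="5p")
            dists.append(loop_distance(w, al))
        assert dists[0] == dists[1]


class TestExtract:
    def test_vector_length_and_determinism(self, perfect_alignment):
        w = build_window(perfect_alignment, 8, arm="5p")
        v1 = extract(w, perfect_alignment)
        v2 = extract(w, perfect_alignment)
        assert v1.shape == (94,)
        assert np.array_equal(v1, v2)

    def test_never_nan_or_inf_on_random_hairpins(self):
        """Feature extraction stays finite over 500 random precursors."""
        ds = generate(SynthSpec(n_precursors=500, seed=77))
        rng = np.random.default_rng(0)
        for rec in ds.records:
            al = align_arms(rec)
            cands = enumerate_candidates(al, rec.id).candidates
            if not cands:
                continue
            for k in rng.choice(len(cands), size=min(2, len(cands)), replace=False):
                v = extract(cands[k], al)
                assert np.isfinite(v).all(), rec.id
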