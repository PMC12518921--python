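import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import band_matrix, partition_of, random_symmetric_pae, single_linkage_oracle
from paeseg import (
    PaeMatrix,
    ResidueLabels,
    SegmentationParams,
    adjust_linkers,
    assign_domains,
    cluster_residues,
    correct_artifacts,
    correct_ends,
    generate_pae,
    is_disordered,
    random_architecture,
    segment_pae,
    symmetrize,
)
from paeseg.segment import DISORDERED, LINKER, NON_DOMAIN


def _sym(values) -> PaeMatrix:
    return PaeMatrix("p", np.asarray(values, dtype=float), symmetrized=True)


def _domain_labels(codes) -> ResidueLabels:
    return ResidueLabels(np.asarray(codes, dtype=np.int64), stage="domain")


class TestClusterResidues:
    def test_requires_two_residues(self):
        with pytest.raises(ValueError, match="protein too short"):
            cluster_residues(_sym([[0.0]]))

    def test_requires_symmetrized(self):
        with pytest.raises(ValueError, match="symmetrized"):
            cluster_residues(PaeMatrix("p", np.zeros((4, 4))))

    def test_zero_distance_blocks_co_cluster(self):
        # two 30-residue groups with identical in-group rows must form
        # exactly two clusters under single linkage, regardless of budget
        n = 60
        group = np.repeat([0, 1], 30)
        m = np.where(group[:, None] == group[None, :], 0.0, 25.0)
        np.fill_diagonal(m, 0.0)
        labels = cluster_residues(_sym(m), SegmentationParams(max_cluster_fraction=0.1))
        assert partition_of(labels.codes) == {frozenset(range(30)), frozenset(range(30, 60))}

    @pytest.mark.parametrize("maxclust", [2, 3, 4])
    def test_matches_bruteforce_oracle(self, rng, maxclust):
        """Flat clusters equal an explicit merge-by-merge single-linkage oracle."""
        for _ in range(20):
            n = int(rng.integers(5, 13))
            m = random_symmetric_pae(rng, n)
            params = SegmentationParams(max_cluster_fraction=maxclust / n)
            labels = cluster_residues(_sym(m), params)
            assert partition_of(labels.codes) == single_linkage_oracle(m, maxclust)


class TestAssignDomains:
    def _labels(self, sizes):
        codes = np.concatenate([np.full(s, k + 1) for k, s in enumerate(sizes)])
        return ResidueLabels(codes, stage="cluster")

    def test_size_threshold(self):
        out = assign_domains(self._labels([180, 140, 3, 2] + [1] * 7))
        assert out.stage == "domain"
        assert set(np.unique(out.codes)) == {NON_DOMAIN, 1, 2}
        assert (out.codes == NON_DOMAIN).sum() == 12
        assert (out.codes[:180] == 1).all() and (out.codes[180:320] == 2).all()

    def test_boundary_is_strictly_greater_than_threshold(self):
        # size 26 is a domain, size 25 is not
        out = assign_domains(self._labels([26, 25]))
        assert (out.codes[:26] == 1).all()
        assert (out.codes[26:] == NON_DOMAIN).all()

    def test_all_singletons_give_no_domain(self):
        codes = np.arange(1, 31)
        out = assign_domains(ResidueLabels(codes, stage="cluster"))
        assert (out.codes == NON_DOMAIN).all()

    def test_domains_numbered_by_position(self):
        # cluster indices permuted: domain 1 must still be the N-terminal one
        codes = np.concatenate([np.full(40, 5), np.full(3, 1), np.full(50, 2)])
        out = assign_domains(ResidueLabels(codes, stage="cluster"))
        assert (out.codes[:40] == 1).all() and (out.codes[43:] == 2).all()


class TestIsDisordered:
    def test_near_diagonal_band_is_disordered(self):
        assert is_disordered((1, 30), _sym(band_matrix(30)))

    def test_fully_compact_is_not(self):
        m = np.full((30, 30), 1.0)
        np.fill_diagonal(m, 0.0)
        assert not is_disordered((1, 30), _sym(m))

    def test_fraction_boundary_is_strict(self):
        # Exactly 24/30 poorly connected residues: 0.8 is not > 0.8.
        # Residues 0..5 form a low clique (5 neighbours each) and each also
        # contacts a distinct far residue (6th neighbour) -> 6 residues
        # exceed the cutoff, 24 do not.
        m = np.full((30, 30), 20.0)
        for i in range(6):
            for j in range(6):
                m[i, j] = 1.0
            m[i, 10 + i] = m[10 + i, i] = 1.0
        np.fill_diagonal(m, 0.0)
        assert not is_disordered((1, 30), _sym(m))
        # drop one extra contact: residue 5 falls to 5 neighbours -> 25/30
        m[5, 15] = m[15, 5] = 20.0
        assert is_disordered((1, 30), _sym(m))

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty region"):
            is_disordered((5, 4), _sym(band_matrix(10)))


class TestCorrectEnds:
    def test_short_terminal_run_absorbed(self):
        labels = _domain_labels([NON_DOMAIN] * 12 + [1] * 50)
        sym = _sym(band_matrix(62))
        out = correct_ends(labels, sym)
        assert (out.codes == 1).all()

    def test_long_loose_run_becomes_disordered(self):
        labels = _domain_labels([NON_DOMAIN] * 35 + [1] * 50)
        sym = _sym(band_matrix(85))
        out = correct_ends(labels, sym)
        assert (out.codes[:35] == DISORDERED).all()
        assert (out.codes[35:] == 1).all()

    def test_long_compact_run_absorbed(self):
        labels = _domain_labels([NON_DOMAIN] * 35 + [1] * 50)
        m = np.full((85, 85), 1.0)
        np.fill_diagonal(m, 0.0)
        out = correct_ends(labels, _sym(m))
        assert (out.codes == 1).all()

    def test_both_termini_handled_independently(self):
        labels = _domain_labels([NON_DOMAIN] * 5 + [1] * 60 + [NON_DOMAIN] * 30)
        sym = _sym(band_matrix(95))
        out = correct_ends(labels, sym)
        assert (out.codes[:65] == 1).all()
        assert (out.codes[65:] == DISORDERED).all()


class TestCorrectArtifacts:
    def test_interior_gap_absorbed(self):
        out = correct_artifacts(_domain_labels([1, 1, 1, 0, 0, 1, 1]))
        assert (out.codes == 1).all()

    def test_enclosed_foreign_domain_absorbed_and_renumbered(self):
        out = correct_artifacts(_domain_labels([1, 1, 2, 1, 1]))
        assert (out.codes == 1).all()

    def test_contiguous_input_is_fixed_point(self):
        codes = [1] * 30 + [0] * 5 + [2] * 40
        out = correct_artifacts(_domain_labels(codes))
        np.testing.assert_array_equal(out.codes, codes)

    def test_interleaved_domains_resolved_deterministically(self):
        # first-seen domain absorbs its whole span; the survivor keeps its
        # outer run and domains are renumbered N->C
        out = correct_artifacts(_domain_labels([2, 2, 1, 2, 2, 1, 1]))
        np.testing.assert_array_equal(out.codes, [1, 1, 1, 1, 1, 2, 2])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=40))
    def test_every_domain_contiguous_afterwards(self, codes):
        out = correct_artifacts(_domain_labels(codes))
        for d in np.unique(out.codes):
            if d > 0:
                idx = np.flatnonzero(out.codes == d)
                assert (np.diff(idx) == 1).all()


def _linker_matrix(linker_supports):
    """220-residue chain: domains 1-150 and 161-220, 10 candidate linker
    residues whose whole-chain low-PAE support is set per residue."""
    L = 220
    m = np.full((L, L), 20.0)
    m[:150, :150] = 1.0
    m[160:, 160:] = 1.0
    for k, target in enumerate(linker_supports):
        r = 150 + k
        cols = [c for c in range(L) if c != r][:target]
        m[r, cols] = 1.0
        m[cols, r] = 1.0
    np.fill_diagonal(m, 0.0)
    labels = _domain_labels([1] * 150 + [NON_DOMAIN] * 10 + [2] * 60)
    return labels, _sym(m)


class TestAdjustLinkers:
    def test_left_edge_joins_domain_until_support_fails(self):
        labels, sym = _linker_matrix([150, 150] + [4] * 8)
        out = adjust_linkers(labels, sym)
        assert (out.codes[150:152] == 1).all()
        assert (out.codes[152:160] == LINKER).all()

    def test_fully_supported_linker_vanishes(self):
        labels, sym = _linker_matrix([150] * 10)
        out = adjust_linkers(labels, sym)
        assert LINKER not in out.codes
        assert (out.codes[:150] == 1).all() and (out.codes[150:160] == 1).all()

    def test_unsupported_linker_unchanged(self):
        labels, sym = _linker_matrix([4] * 10)
        out = adjust_linkers(labels, sym)
        assert (out.codes[150:160] == LINKER).all()

    def test_walks_never_pass_each_other(self):
        labels, sym = _linker_matrix([150] * 9 + [4])
        out = adjust_linkers(labels, sym)
        # left walk consumes 9, right walk fails at its first residue
        assert (out.codes[150:159] == 1).all()
        assert out.codes[159] == LINKER


class TestSegmentPae:
    def test_two_domain_recovery(self, two_domain):
        pae, truth = two_domain
        seg = segment_pae(pae)
        assert seg.n_domains == 2
        pred = [(r.start, r.end) for r in seg.domains]
        ref = [(r.start, r.end) for r in truth.domains]
        for (ps_, pe), (rs, re) in zip(pred, ref):
            assert abs(ps_ - rs) <= 2 and abs(pe - re) <= 2

    def test_disordered_terminus_recovered(self, disordered_n_protein):
        pae, truth = disordered_n_protein
        seg = segment_pae(pae)
        kinds = [r.kind for r in seg.regions]
        assert kinds == ["disordered", "domain"]
        assert seg.regions[0].end == 40

    def test_deterministic(self, two_domain):
        pae, _ = two_domain
        assert segment_pae(pae) == segment_pae(pae)

    def test_regions_tile_protein(self):
        for seed in range(1, 11):
            pae, truth = generate_pae(random_architecture(seed))
            seg = segment_pae(pae)  # Segmentation validates the tiling itself
            assert seg.length == truth.length
            assert seg.regions[0].start == 1 and seg.regions[-1].end == seg.length

    def test_cluster_relabeling_does_not_change_result(self, two_domain):
        pae, _ = two_domain
        params = SegmentationParams()
        sym = symmetrize(pae)
        labels = cluster_residues(sym, params)
        k = int(labels.codes.max())
        perm = np.concatenate([[0], np.random.default_rng(5).permutation(k) + 1])
        permuted = ResidueLabels(perm[labels.codes], stage="cluster")

        def finish(lab):
            lab = assign_domains(lab, params)
            lab = correct_ends(lab, sym, params)
            lab = correct_artifacts(lab)
            return adjust_linkers(lab, sym, params)

        np.testing.assert_array_equal(finish(labels).codes, finish(permuted).codes)

    def test_raising_domain_threshold_never_adds_domains(self):
        for seed in range(1, 8):
            pae, _ = generate_pae(random_architecture(seed))
            counts = [
                segment_pae(pae, SegmentationParams(min_domain_cluster=t)).n_domains
                for t in (25, 35, 50)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_lysin_like_architectures_give_one_to_four_domains(self):
        for seed in range(1, 11):
            arch = random_architecture(seed)
            seg = segment_pae(generate_pae(arch, noise_sd=0.0)[0])
            assert 1 <= seg.n_domains <= 4

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="protein too short"):
            segment_pae(PaeMatrix("p", np.zeros((1, 1))))
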