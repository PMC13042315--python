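"""Simulator contracts: determinism, divergence targets, mixing arithmetic."""

import numpy as np
import pytest

from bafscreen import (
    MixtureSpec,
    SiteRecord,
    mix_fastq,
    simulate_lineage_panel,
    simulate_panel,
    simulate_read_counts,
    simulate_reference,
    simulate_strain,
)
from bafscreen._seq import encode
from bafscreen.io import read_fastq, write_fastq
from bafscreen.simulate import most_divergent_pair


def hamming(panel, a, b):
    sa = np.concatenate([panel.strains[a].haplotypes[n][0] for n in panel.reference.names])
    sb = np.concatenate([panel.strains[b].haplotypes[n][0] for n in panel.reference.names])
    return (sa != sb).mean()


class TestPanel:
    def test_zero_divergence_gives_reference_copies(self, small_reference):
        panel = simulate_panel(small_reference, 4, 0.0, seed=1)
        for strain in panel.strains.values():
            for name in small_reference.names:
                assert np.array_equal(
                    strain.haplotypes[name][0], small_reference.chrom_array(name)
                )

    def test_determinism(self, small_reference):
        p1 = simulate_panel(small_reference, 5, 0.005, seed=42)
        p2 = simulate_panel(small_reference, 5, 0.005, seed=42)
        for sid in p1.strains:
            for name in small_reference.names:
                assert np.array_equal(
                    p1.strains[sid].haplotypes[name], p2.strains[sid].haplotypes[name]
                )
        assert p1.tree.as_string("newick") == p2.tree.as_string("newick")

    def test_mean_pairwise_divergence_near_target(self, small_reference):
        panel = simulate_panel(small_reference, 20, 0.005, seed=1)
        ids = panel.strain_ids
        divs = [
            hamming(panel, ids[i], ids[j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        ]
        assert 0.0025 <= np.mean(divs) <= 0.01

    def test_too_few_strains_rejected(self, small_reference):
        with pytest.raises(ValueError):
            simulate_panel(small_reference, 3, 0.005, seed=1)

    def test_lineage_panel_mates_closer_than_lineages(self, lineage_panel):
        # within-lineage divergence must be well below between-lineage
        within = hamming(lineage_panel, "L01_s1", "L01_s2")
        between = hamming(lineage_panel, "L01_s1", "L02_s1")
        assert within < between
        assert lineage_panel.lineage_members("L03_s1") == {"L03_s1", "L03_s2"}


class TestStrain:
    def test_haploid_has_no_heterozygosity(self, small_panel):
        s = simulate_strain(small_panel, "strain_01", 1, heterozygosity=0.01, seed=3)
        assert s.ploidy == 1
        assert s.heterozygous_site_count() == 0

    def test_diploid_het_site_count_near_target(self, small_panel):
        s = simulate_strain(small_panel, "strain_02", 2, heterozygosity=0.005, seed=3)
        expected = 0.005 * small_panel.reference.total_length
        assert abs(s.heterozygous_site_count() - expected) <= 0.3 * expected

    def test_tetraploid_shapes(self, small_panel):
        s = simulate_strain(small_panel, "strain_03", 4, heterozygosity=0.005, seed=3)
        for name in small_panel.reference.names:
            assert s.haplotypes[name].shape == (
                4,
                small_panel.reference.chrom_length(name),
            )

    def test_unknown_lineage_rejected(self, small_panel):
        with pytest.raises(KeyError):
            simulate_strain(small_panel, "no_such_strain", 2, seed=0)


class TestReadCounts:
    def test_counts_conserved_and_deterministic(self, small_panel):
        a, b = most_divergent_pair(small_panel)
        spec = MixtureSpec(a, b, 0.1, 60.0, seed=9)
        r1 = simulate_read_counts(
            small_panel.strains[a], small_panel.strains[b], spec
        )
        r2 = simulate_read_counts(
            small_panel.strains[a], small_panel.strains[b], spec
        )
        assert r1 == r2
        assert all(0 <= r.alt_depth <= r.depth for r in r1)

    def test_contamination_without_contaminant_rejected(self, small_panel):
        spec = MixtureSpec("strain_01", None, 0.1, 60.0, seed=1)
        with pytest.raises(ValueError):
            simulate_read_counts(small_panel.strains["strain_01"], None, spec)

    def test_clean_haploid_baf_near_one(self, small_panel):
        a, _ = most_divergent_pair(small_panel)
        spec = MixtureSpec(a, None, 0.0, 80.0, seed=5)
        recs = simulate_read_counts(
            small_panel.strains[a], None, spec, repeat_fraction=0.0
        )
        bafs = np.array([r.baf for r in recs])
        assert np.median(bafs) > 0.97  # 1 - error rate, minus noise

    def test_mixing_linearity_closed_form(self, big_panel):
        # recipient hom-alt, contaminant hom-ref sites: E[BAF] = (1-c)(1-e)+c*e
        c, eps = 0.2, 0.002
        a, b = most_divergent_pair(big_panel)
        rec, con = big_panel.strains[a], big_panel.strains[b]
        recs = simulate_read_counts(
            rec, con, MixtureSpec(a, b, c, 80.0, seed=8), repeat_fraction=0.0
        )
        # recipient-specific sites: recipient alt, contaminant ref
        ref, chap, rhap = {}, {}, {}
        keep = []
        for r in recs:
            arr = big_panel.reference.chrom_array(r.chrom)
            i = r.pos - 1
            rec_alt = rec.haplotypes[r.chrom][0, i] != arr[i]
            con_ref = con.haplotypes[r.chrom][0, i] == arr[i]
            if rec_alt and con_ref:
                keep.append(r.baf)
        assert len(keep) >= 10_000
        expected = (1 - c) * (1 - eps) + c * eps
        assert abs(np.mean(keep) - expected) < 0.003

    def test_full_replacement_matches_pure_contaminant(self, small_panel):
        a, b = most_divergent_pair(small_panel)
        rec, con = small_panel.strains[a], small_panel.strains[b]
        full = simulate_read_counts(
            rec, con, MixtureSpec(a, b, 1.0, 80.0, seed=2), repeat_fraction=0.0
        )
        pure = simulate_read_counts(
            con, None, MixtureSpec(b, None, 0.0, 80.0, seed=2), repeat_fraction=0.0
        )
        # same high-BAF site set: contaminant SNPs dominate both
        def high_sites(records):
            return {(r.chrom, r.pos) for r in records if r.baf > 0.5}

        shared = high_sites(full) & high_sites(pure)
        assert len(shared) > 0.9 * len(high_sites(pure))

    def test_all_sites_mode_covers_genome(self, small_panel):
        a, _ = most_divergent_pair(small_panel)
        recs = simulate_read_counts(
            small_panel.strains[a],
            None,
            MixtureSpec(a, None, 0.0, 30.0, seed=4),
            all_sites=True,
            repeat_fraction=0.0,
        )
        assert len(recs) == small_panel.reference.total_length


class TestMixFastq:
    def _write_library(self, tmp_path, prefix, n):
        r1 = [(f"{prefix}_{i}/1", "ACGT" * 10, "I" * 40) for i in range(n)]
        r2 = [(f"{prefix}_{i}/2", "TGCA" * 10, "I" * 40) for i in range(n)]
        p1, p2 = tmp_path / f"{prefix}_1.fastq", tmp_path / f"{prefix}_2.fastq"
        write_fastq(r1, p1)
        write_fastq(r2, p2)
        return str(p1), str(p2)

    def test_mix_counts_and_pairing(self, tmp_path):
        la = self._write_library(tmp_path, "liba", 1000)
        lb = self._write_library(tmp_path, "libb", 200)
        out = (str(tmp_path / "o1.fastq"), str(tmp_path / "o2.fastq"))
        na, nb = mix_fastq(la, lb, 1000, c=0.1, seed=1, out_pair=out)
        assert (na, nb) == (900, 100)
        o1, o2 = read_fastq(out[0]), read_fastq(out[1])
        assert len(o1) == len(o2) == 1000
        assert sum(name.startswith("libb") for name, _, _ in o1) == 100
        # mate pairing preserved: same ordering of read ids in both files
        assert [n.split("/")[0] for n, _, _ in o1] == [
            n.split("/")[0] for n, _, _ in o2
        ]

    def test_pure_subsample_at_c_zero(self, tmp_path):
        la = self._write_library(tmp_path, "liba", 50)
        lb = self._write_library(tmp_path, "libb", 50)
        out = (str(tmp_path / "o1.fastq"), str(tmp_path / "o2.fastq"))
        mix_fastq(la, lb, 30, c=0.0, seed=3, out_pair=out)
        names = {n for n, _, _ in read_fastq(out[0])}
        assert all(n.startswith("liba") for n in names)

    def test_insufficient_reads_error_names_library(self, tmp_path):
        la = self._write_library(tmp_path, "liba", 10)
        lb = self._write_library(tmp_path, "libb", 10)
        out = (str(tmp_path / "o1.fastq"), str(tmp_path / "o2.fastq"))
        with pytest.raises(ValueError, match="liba"):
            mix_fastq(la, lb, 100, c=0.0, seed=1, out_pair=out)
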