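"""MLST scheme loading, allele matching at the 95/95 rule and ST calling."""

import pytest

from bactasm.assemble import Assembly, Contig
from bactasm.mlst import (
    EXACT,
    MATCH,
    MISSING,
    MULTIPLE,
    NOVEL,
    PARTIAL,
    find_allele,
    load_scheme,
    make_synthetic_scheme,
    type_assembly,
    write_scheme,
)
from bactasm.seqio import revcomp
from bactasm.sim import SimSpec, simulate_genome


@pytest.fixture(scope="module")
def scheme_setup(tmp_path_factory):
    spec = SimSpec(genome_length=8000, seed=9, error_rate=0.0)
    genome = simulate_genome(spec)
    scheme, positions = make_synthetic_scheme(genome, n_loci=7, allele_length=400, seed=9)
    directory = tmp_path_factory.mktemp("scheme")
    write_scheme(scheme, directory)
    return {"genome": genome, "scheme": scheme, "positions": positions,
            "dir": directory}


def mutate(seq: str, n: int) -> str:
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(seq)
    step = len(seq) // (n + 1)
    for i in range(n):
        pos = (i + 1) * step
        out[pos] = swap[out[pos]]
    return "".join(out)


class TestLoadScheme:
    def test_round_trip(self, scheme_setup):
        loaded = load_scheme(scheme_setup["dir"])
        assert loaded.loci == scheme_setup["scheme"].loci
        assert loaded.alleles == scheme_setup["scheme"].alleles
        assert loaded.profiles == scheme_setup["scheme"].profiles

    def test_missing_locus_file_is_error(self, scheme_setup, tmp_path):
        import shutil

        broken = tmp_path / "broken"
        shutil.copytree(scheme_setup["dir"], broken)
        (broken / "locus3.fas").unlink()
        with pytest.raises(FileNotFoundError, match="locus3"):
            load_scheme(broken)

    def test_profile_with_unknown_allele_is_error(self, scheme_setup, tmp_path):
        import shutil

        broken = tmp_path / "badprofile"
        shutil.copytree(scheme_setup["dir"], broken)
        with open(broken / "profiles.tsv", "a") as handle:
            handle.write("99\t" + "\t".join(["42"] * 7) + "\n")
        with pytest.raises(ValueError, match="unknown allele"):
            load_scheme(broken)


class TestFindAllele:
    def test_verbatim_allele_is_exact(self, scheme_setup):
        scheme = scheme_setup["scheme"]
        asm = Assembly([Contig("c1", scheme_setup["genome"].seq)])
        call = find_allele(asm, "locus1", scheme.alleles["locus1"])
        assert call.status == EXACT and call.allele == 1
        assert call.percent_identity == 100.0 and call.percent_length == 100.0

    @pytest.mark.parametrize(
        "n_subs,expected_status",
        [
            (0, EXACT),
            (8, MATCH),    # 98 % identity
            (20, MATCH),   # exactly 95.0 %: the boundary is inclusive
            (21, PARTIAL), # 94.75 %: just under the threshold
            (24, PARTIAL), # 94 % identity, full length
        ],
    )
    def test_identity_threshold_sharpness(self, scheme_setup, n_subs, expected_status):
        scheme = scheme_setup["scheme"]
        allele = scheme.alleles["locus2"][1]  # 400 bases
        assert len(allele) == 400
        embedded = "T" * 600 + mutate(allele, n_subs) + "G" * 600
        call = find_allele(Assembly([Contig("c1", embedded)]), "locus2",
                           {1: allele})
        assert call.status == expected_status
        if expected_status in (EXACT, MATCH):
            assert call.allele == 1
        else:
            assert call.allele is None

    def test_absent_locus_is_missing(self, scheme_setup):
        scheme = scheme_setup["scheme"]
        call = find_allele(
            Assembly([Contig("c1", "AT" * 400)]), "locus1", scheme.alleles["locus1"]
        )
        assert call.status == MISSING

    def test_two_alleles_on_two_contigs_flag_multiple(self, scheme_setup):
        scheme = scheme_setup["scheme"]
        a1 = scheme.alleles["locus1"][1]
        a2 = scheme.alleles["locus1"][2]
        asm = Assembly([
            Contig("c1", "T" * 200 + a1 + "G" * 200),
            Contig("c2", "A" * 200 + a2 + "C" * 200),
        ])
        call = find_allele(asm, "locus1", scheme.alleles["locus1"])
        assert call.status == MULTIPLE


class TestTyping:
    def test_embedded_profile_round_trips_to_st1(self, scheme_setup):
        asm = Assembly([Contig("c1", scheme_setup["genome"].seq)])
        result = type_assembly(asm, scheme_setup["scheme"])
        assert result.st == 1 and not result.contaminated
        assert all(c.status == EXACT for c in result.calls)

    def test_strand_invariance(self, scheme_setup):
        asm = Assembly([Contig("c1", revcomp(scheme_setup["genome"].seq))])
        result = type_assembly(asm, scheme_setup["scheme"])
        assert result.st == 1

    def test_missing_locus_gives_no_st(self, scheme_setup):
        genome = scheme_setup["genome"].seq
        start, end = scheme_setup["positions"]["locus4"]
        gutted = genome[:start] + genome[end:]
        result = type_assembly(Assembly([Contig("c1", gutted)]),
                               scheme_setup["scheme"])
        assert result.st is None
        statuses = {c.locus: c.status for c in result.calls}
        assert statuses["locus4"] in (MISSING, PARTIAL)

    def test_unknown_vector_is_novel(self, scheme_setup):
        scheme = scheme_setup["scheme"]
        genome = scheme_setup["genome"].seq
        # replace locus1 with its variant allele 2 -> vector (2,1,1,...) is
        # not in the profile table
        start, end = scheme_setup["positions"]["locus1"]
        hybrid = genome[:start] + scheme.alleles["locus1"][2] + genome[end:]
        result = type_assembly(Assembly([Contig("c1", hybrid)]), scheme)
        assert result.st == NOVEL

    def test_contamination_sets_flag(self, scheme_setup):
        scheme = scheme_setup["scheme"]
        genome = scheme_setup["genome"].seq
        extra = "T" * 300 + scheme.alleles["locus1"][2] + "G" * 300
        asm = Assembly([Contig("c1", genome), Contig("c2", extra)])
        result = type_assembly(asm, scheme)
        assert result.contaminated
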