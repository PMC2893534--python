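import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mlpaprobe import ProbeCandidate, ScreenConfig, ThermoConfig


def make_candidate(lhs: str, rhs: str, target_id: str = "syn") -> ProbeCandidate:
    """Candidate standing alone (its implied target is exactly lhs+rhs)."""
    return ProbeCandidate(
        target_id=target_id, ligation_pos=len(lhs), lhs=lhs, rhs=rhs
    )


# G/T-only 20-mer: GC fraction 0.5, and with no C or A it cannot base-pair
# with itself, so hairpin and self-dimer ΔG are both "none".
STRUCTURELESS_20 = "GGTTGGTTGGTTGGTTGGTT"


@pytest.fixture
def lenient_screen() -> ScreenConfig:
    """Thresholds the structureless G/T test sequences comfortably pass."""
    return ScreenConfig(
        tm_min=40.0, tm_opt=45.0, gc_min=0.35, gc_max=0.65,
        lhs_len_range=(20, 30), rhs_len_range=(20, 30),
    )


@pytest.fixture
def thermo_cfg() -> ThermoConfig:
    return ThermoConfig()


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20100521)


def random_seq(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def plant_ms_fixture(out_dir, seed: int = 20100521):
    """A CpG-free toy genome with one embedded target carrying exactly two
    HhaI (GCGC) sites, one of which contains a planted SNP.

    CpG-free background means no methylation-sensitive recognition site can
    occur anywhere except the planted blocks, so site counts per candidate
    are fully known. Returns paths plus the ground truth (target-local site
    offsets and the SNP offset).
    """
    from pathlib import Path

    from mlpaprobe.seq_core import random_dna

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    genome = random_dna(rng, 3000, cpg_free=True)
    t_start, t_len = 1000, 110
    site_offsets = (30, 85)  # target-local starts of the GCGC sites
    for off in site_offsets:
        g = t_start + off
        # TT / TT borders prevent accidental overlapping sites
        genome = genome[: g - 2] + "TT" + "GCGC" + "TT" + genome[g + 6 :]
    snp_offset = site_offsets[1] + 1  # inside the second site
    snp_pos = t_start + snp_offset
    target = genome[t_start : t_start + t_len]

    genome_fa = out_dir / "genome.fa"
    genome_fa.write_text(">chrT\n" + genome + "\n")
    targets_fa = out_dir / "targets.fa"
    targets_fa.write_text(">tgt1\n" + target + "\n")
    vcf = out_dir / "variants.vcf"
    ref = genome[snp_pos]
    alt = "A" if ref != "A" else "T"
    vcf.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=chrT>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        f"chrT\t{snp_pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n"
    )
    return {
        "genome": genome_fa,
        "targets": targets_fa,
        "vcf": vcf,
        "site_offsets": site_offsets,
        "snp_offset": snp_offset,
        "target_start": t_start,
        "target_seq": target,
    }


def ms_run_config():
    """Lenient-but-realistic thresholds for the toy MS-MLPA fixture."""
    from mlpaprobe import RunConfig, ScreenConfig

    screen = ScreenConfig(
        tm_min=40.0, tm_opt=45.0, gc_min=0.2, gc_max=0.8,
        lhs_len_range=(21, 24), rhs_len_range=(21, 24),
    )
    return RunConfig(screen=screen, enzyme="HhaI")
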