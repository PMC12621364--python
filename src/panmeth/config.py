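"""Configuration for the synthetic parent-progeny trio generator.

The trio mimics a hybrid grapevine design: two diploid parents (CF with
haplotypes CF1/CF2, SB with SB1/SB2) and a progeny CS that carries one
haplotype inherited from each parent (CSCF from CF, CSSB from SB).  Each
cultivar is observed through several vegetatively propagated clones that
share the genotype but have slightly divergent methylomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

HAPLOTYPES = ("CF1", "CF2", "SB1", "SB2", "CSCF", "CSSB")
PARENTAL_HAPLOTYPES = ("CF1", "CF2", "SB1", "SB2")
CULTIVARS = ("CF", "SB", "CS")
CULTIVAR_OF = {
    "CF1": "CF",
    "CF2": "CF",
    "SB1": "SB",
    "SB2": "SB",
    "CSCF": "CS",
    "CSSB": "CS",
}
HAPS_OF_CULTIVAR = {
    "CF": ("CF1", "CF2"),
    "SB": ("SB1", "SB2"),
    "CS": ("CSCF", "CSSB"),
}
CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class TrioConfig:
    """All knobs of the synthetic trio.

    Rates are per-bp probabilities; methylation levels are percentages.
    ``context_meth_prob`` gives the probability that a cytosine (or an
    ancestral block, see ``state_block_bp``) is in the methylated state
    per sequence context; these are free parameters of the generator, not
    estimates of any real genome.
    """

    n_chromosomes: int = 1
    chrom_length: int = 50_000
    gc_content: float = 0.4
    snp_rate: float = 0.005
    indel_rate: float = 0.0005
    sv_count: int = 2
    clones_per_cultivar: int = 3
    mean_coverage: float = 30.0
    epimutation_rate: float = 0.01
    clone_noise_sd: float = 2.0
    level_methylated: float = 80.0
    level_unmethylated: float = 2.0
    context_meth_prob: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.5, "CHG": 0.3, "CHH": 0.05}
    )
    seed: int = 0

    # -- optional scenario machinery ------------------------------------
    # Methylation states drawn per ancestral block of this many bp rather
    # than per site (None = i.i.d. per site).  Blocked states make truth
    # DMRs unambiguous.
    state_block_bp: int | None = None
    # Fraction of blocks planted with a full parental differential
    # (methylated in the first group, unmethylated in the second).
    planted_diff_fraction: float = 0.0
    planted_diff_context: str = "CG"
    # 'cultivar': CF haplotypes vs SB haplotypes; 'intra': hap1 vs hap2
    # within each parent.
    planted_diff_mode: str = "cultivar"
    # Single-reference-bias scenario: one methylation state per ancestral
    # block shared by all contexts and all haplotypes, enabling C>T
    # planting conditioned on the methylated state.
    ancestral_block_states: bool = False
    # Probability that an ancestral C/G inside a methylated block carries
    # a C>T (G>A) transition on the SB lineage.
    ct_snp_fraction: float = 0.0
    # Number of inheritance breakpoints per CS haplotype per chromosome
    # (0 = whole-haplotype inheritance).
    recombination_breakpoints: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gc_content",
            "snp_rate",
            "indel_rate",
            "epimutation_rate",
            "planted_diff_fraction",
            "ct_snp_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for ctx, p in self.context_meth_prob.items():
            if ctx not in CONTEXTS:
                raise ValueError(f"unknown context {ctx!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"context_meth_prob[{ctx}] must be in [0, 1]")
        if self.chrom_length < 2000:
            raise ValueError("chrom_length must be >= 2000")
        if self.clones_per_cultivar < 2:
            raise ValueError("clones_per_cultivar must be >= 2")
        if self.planted_diff_mode not in ("cultivar", "intra"):
            raise ValueError("planted_diff_mode must be 'cultivar' or 'intra'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
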