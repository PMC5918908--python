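"""Forward simulator of a gene locus flanked by two segmental duplications.

The simulated history mirrors the mutational model inferred for a
NAHR-deleted gene in two sister species (here labelled ``human`` and
``chimp`` by default):

1. An ancestral segment is duplicated into two paralogs, SD1 and SD2, which
   accumulate substitutions independently for a configurable pre-split time.
2. Gene-conversion tracts copy sequence between the paralogs (default
   direction SD1 -> SD2) shortly before the fusion events, creating local
   islands of high SD1-SD2 identity; NAHR requires such homology, so fusion
   breakpoints are constrained to lie inside a converted tract by default.
3. The gene is deleted by NAHR, fusing SD1[0:b) to SD2[b:L). Under the
   ``recurrent`` scenario each lineage experiences its own fusion after the
   species split (possibly at different breakpoints); under ``ibd`` a single
   fusion predates the split and both species inherit the same fused
   haplotype (trans-species polymorphism through incomplete lineage
   sorting).
4. Optional lineage-specific conversion events (e.g. a post-split SD1/SD2
   sequence exchange in one lineage) are applied to the reference paralogs
   at the species split.

Substitutions are Jukes-Cantor single-nucleotide replacement events with no
indels: event counts per branch are Poisson(rate x years x sites), each
event hits a uniform position and replaces the current base by one of the
other three. There are no indels, so alignment columns equal sequence
coordinates (0-based, half-open).

Randomness: one ``numpy.random.Generator`` seeded from ``SimConfig.seed``
drives every draw. Stream order is fixed and documented in
:func:`simulate_locus` so that a seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from sdfusion.alignment import SDAlignment, SDRecord, decode

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimConfigError",
    "simulate_locus",
    "evolve_branch",
    "write_truth",
    "read_truth",
]

DIRECTIONS = ("sd1_to_sd2", "sd2_to_sd1", "swap")


class SimConfigError(ValueError):
    """Raised for an invalid or internally inconsistent simulation config."""


def _normalize_tracts(tracts, sd_length: int, what: str) -> list[tuple[int, int, str]]:
    """Validate tract tuples and fill in the default conversion direction."""
    out: list[tuple[int, int, str]] = []
    for t in tracts:
        if len(t) == 2:
            start, end, direction = int(t[0]), int(t[1]), "sd1_to_sd2"
        elif len(t) == 3:
            start, end, direction = int(t[0]), int(t[1]), str(t[2])
        else:
            raise SimConfigError(f"{what} tract {t!r} is not (start, end[, direction])")
        if direction not in DIRECTIONS:
            raise SimConfigError(f"{what} tract direction {direction!r} not in {DIRECTIONS}")
        if not (0 <= start < end <= sd_length):
            raise SimConfigError(f"{what} tract [{start}, {end}) outside [0, {sd_length})")
        out.append((start, end, direction))
    out.sort()
    for (s0, e0, _), (s1, _, _) in zip(out, out[1:]):
        if s1 < e0:
            raise SimConfigError(f"{what} tracts overlap at [{s1}, {e0})")
    return out


@dataclass
class SimConfig:
    """Parameters of a two-species SD-flanked locus simulation.

    Times are in years before present except ``t_fusion_a``/``t_fusion_b``
    under the ``ibd`` scenario, where the (single, shared) fusion is placed
    ``t_fusion_a`` years *before the species split* so that the fused
    haplotypes coalesce deeper than the split. ``t_pre_split`` is the time
    between the SD1/SD2 duplication and the species split and sets the
    baseline paralog divergence.
    """

    seed: int = 0
    sd_length: int = 12541
    per_site_rate: float = 1e-9
    t_div: float = 6.3e6
    t_pre_split: float = 3e7
    t_fusion_a: float | None = None
    t_fusion_b: float | None = None
    t_ibd_star: float = 4e5
    scenario: str = "recurrent"
    n_haplotypes_per_species: int = 7
    species: tuple[str, str] = ("human", "chimp")
    ancestral_conversion_tracts: Sequence = ((1500, 3500), (8000, 11000))
    lineage_conversion_tracts: Mapping[str, Sequence] = field(
        default_factory=lambda: {"chimp": [(4001, 7500, "swap")]}
    )
    breakpoint_a: int | None = None
    breakpoint_b: int | None = None
    require_breakpoint_in_tract: bool = True

    def __post_init__(self) -> None:
        if self.scenario not in ("recurrent", "ibd"):
            raise SimConfigError(f"scenario must be recurrent|ibd, got {self.scenario!r}")
        if self.sd_length < 2:
            raise SimConfigError("sd_length must be >= 2")
        if self.per_site_rate < 0:
            raise SimConfigError("per_site_rate must be >= 0")
        if self.t_div <= 0 or self.t_pre_split <= 0:
            raise SimConfigError("t_div and t_pre_split must be positive")
        if len(self.species) != 2 or len(set(self.species)) != 2:
            raise SimConfigError("exactly two distinct species labels required")
        if self.n_haplotypes_per_species < 1:
            raise SimConfigError("n_haplotypes_per_species must be >= 1")
        # scenario-dependent fusion-time defaults: a recent post-split fusion
        # per lineage (recurrent) vs a fusion well before the split whose
        # polymorphism survives in both species (ibd)
        if self.t_fusion_a is None:
            self.t_fusion_a = 4e5 if self.scenario == "recurrent" else 5e6
        if self.t_fusion_b is None:
            self.t_fusion_b = self.t_fusion_a if self.scenario == "ibd" else 4e5
        if self.scenario == "recurrent":
            for t in (self.t_fusion_a, self.t_fusion_b):
                if not (0 < t < self.t_div):
                    raise SimConfigError(
                        "recurrent scenario needs 0 < t_fusion < t_div "
                        f"(got {t}, t_div={self.t_div})"
                    )
        else:
            if not (0 < self.t_fusion_a <= self.t_pre_split):
                raise SimConfigError(
                    "ibd scenario needs 0 < t_fusion_a <= t_pre_split "
                    "(fusion time before the split)"
                )
            if not (0 < self.t_ibd_star <= self.t_div):
                raise SimConfigError("ibd scenario needs 0 < t_ibd_star <= t_div")
        self.ancestral_conversion_tracts = _normalize_tracts(
            self.ancestral_conversion_tracts, self.sd_length, "ancestral"
        )
        self.lineage_conversion_tracts = {
            lin: _normalize_tracts(tr, self.sd_length, f"lineage {lin!r}")
            for lin, tr in dict(self.lineage_conversion_tracts).items()
        }
        for lin in self.lineage_conversion_tracts:
            if lin not in self.species:
                raise SimConfigError(f"lineage {lin!r} not among species {self.species}")
        for bp in (self.breakpoint_a, self.breakpoint_b):
            if bp is not None:
                self._check_breakpoint(int(bp))

    def _check_breakpoint(self, bp: int) -> None:
        if not (0 < bp < self.sd_length):
            raise SimConfigError(f"breakpoint {bp} outside (0, {self.sd_length})")
        if self.require_breakpoint_in_tract and self.ancestral_conversion_tracts:
            if not any(s <= bp < e for s, e, _ in self.ancestral_conversion_tracts):
                raise SimConfigError(
                    f"breakpoint {bp} lies outside every ancestral conversion tract; "
                    "NAHR requires local homology "
                    "(set require_breakpoint_in_tract=False to override)"
                )


@dataclass
class SimTruth:
    """Ground truth of one simulated locus."""

    scenario: str
    seed: int
    breakpoint_a: int
    breakpoint_b: int
    ancestral_conversion_tracts: list[tuple[int, int, str]]
    lineage_conversion_tracts: dict[str, list[tuple[int, int, str]]]
    genealogy: str  # newick, branch lengths in years; upstream-of-breakpoint segment

    @property
    def breakpoints(self) -> tuple[int, int]:
        return (self.breakpoint_a, self.breakpoint_b)


def evolve_branch(
    seq: np.ndarray, years: float, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Evolve a coded sequence along one branch; return (child, n_events).

    Draws ``K ~ Poisson(rate * years * len(seq))`` replacement events, each at
    a uniform site, replacing the current base by one of the other three
    (Jukes-Cantor). Events are applied sequentially, so multiple hits at one
    site are handled naturally.
    """
    out = seq.copy()
    lam = rate * years * out.size
    k = int(rng.poisson(lam)) if lam > 0 else 0
    if k:
        pos = rng.integers(0, out.size, size=k)
        shift = rng.integers(1, 4, size=k).astype(np.uint8)
        for p, s in zip(pos, shift):
            out[p] = (out[p] + s) % 4
    return out, k


def _apply_tracts(sd1: np.ndarray, sd2: np.ndarray, tracts) -> None:
    """Apply gene-conversion tracts in place (non-reciprocal copy or swap)."""
    for start, end, direction in tracts:
        if direction == "sd1_to_sd2":
            sd2[start:end] = sd1[start:end]
        elif direction == "sd2_to_sd1":
            sd1[start:end] = sd2[start:end]
        else:  # swap: reciprocal exchange
            tmp = sd1[start:end].copy()
            sd1[start:end] = sd2[start:end]
            sd2[start:end] = tmp


def _draw_breakpoint(cfg: SimConfig, rng: np.random.Generator) -> int:
    """Uniform draw within the downstream converted tract, else uniform.

    NAHR needs local homology, so default breakpoints fall inside a
    converted tract; the last (downstream) tract is used so that the fused
    haplotype is SD1-derived upstream and SD2-derived downstream of the
    switch, the configuration the region partition assumes.
    """
    tracts = cfg.ancestral_conversion_tracts
    if cfg.require_breakpoint_in_tract and tracts:
        s, e, _ = tracts[-1]
        return int(rng.integers(max(s, 1), min(e, cfg.sd_length - 1)))
    return int(rng.integers(1, cfg.sd_length))


def _star(node_labels: Sequence[str], blen: float) -> str:
    return ",".join(f"{lab}:{blen:g}" for lab in node_labels)


def simulate_locus(config: SimConfig) -> tuple[SDAlignment, SimTruth]:
    """Simulate the locus and return the alignment plus its ground truth.

    Stream order (fixed; a seed fully determines the output):

    1. ancestral root sequence (uniform bases),
    2. breakpoint draw(s) if not configured (species A then B; one draw
       under ``ibd``),
    3. SD1 then SD2 pre-split branches,
    4. per species in ``config.species`` order: SD1 branch to fusion, SD2
       branch to fusion, SD1 and SD2 branches to present, fused haplotypes
       1..n (recurrent); the ibd stream order is the analogous
       ancestor-first, species-in-order traversal.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.sd_length
    rate = cfg.per_site_rate

    root = rng.integers(0, 4, size=L, dtype=np.uint8)

    if cfg.scenario == "recurrent":
        bp_a = int(cfg.breakpoint_a) if cfg.breakpoint_a is not None else _draw_breakpoint(cfg, rng)
        bp_b = int(cfg.breakpoint_b) if cfg.breakpoint_b is not None else _draw_breakpoint(cfg, rng)
    else:
        if cfg.breakpoint_a is not None:
            bp_a = int(cfg.breakpoint_a)
        elif cfg.breakpoint_b is not None:
            bp_a = int(cfg.breakpoint_b)
        else:
            bp_a = _draw_breakpoint(cfg, rng)
        bp_b = bp_a
        if cfg.breakpoint_a is not None and cfg.breakpoint_b is not None \
                and int(cfg.breakpoint_a) != int(cfg.breakpoint_b):
            raise SimConfigError("ibd scenario admits a single shared breakpoint")

    sp_a, sp_b = cfg.species
    n = cfg.n_haplotypes_per_species
    records: list[SDRecord] = []

    def rec(species: str, role: str, hap_id: str, codes: np.ndarray) -> None:
        records.append(SDRecord(species, role, hap_id, decode(codes)))

    if cfg.scenario == "recurrent":
        # paralogs diverge for the full pre-split time, conversion at the split
        sd1_anc, _ = evolve_branch(root, cfg.t_pre_split, rate, rng)
        sd2_anc, _ = evolve_branch(root, cfg.t_pre_split, rate, rng)
        _apply_tracts(sd1_anc, sd2_anc, cfg.ancestral_conversion_tracts)

        for species, t_fus, bp in ((sp_a, cfg.t_fusion_a, bp_a), (sp_b, cfg.t_fusion_b, bp_b)):
            sd1_s = sd1_anc.copy()
            sd2_s = sd2_anc.copy()
            _apply_tracts(sd1_s, sd2_s, cfg.lineage_conversion_tracts.get(species, ()))
            sd1_fus, _ = evolve_branch(sd1_s, cfg.t_div - t_fus, rate, rng)
            sd2_fus, _ = evolve_branch(sd2_s, cfg.t_div - t_fus, rate, rng)
            sd1_ref, _ = evolve_branch(sd1_fus, t_fus, rate, rng)
            sd2_ref, _ = evolve_branch(sd2_fus, t_fus, rate, rng)
            rec(species, "SD1", "ref", sd1_ref)
            rec(species, "SD2", "ref", sd2_ref)
            founder = np.concatenate([sd1_fus[:bp], sd2_fus[bp:]])
            for i in range(1, n + 1):
                hap, _ = evolve_branch(founder, t_fus, rate, rng)
                rec(species, "fusedSD", f"f{i}", hap)

        # genealogy of the SD1-derived segment [0, breakpoint)
        def sp_clade(species: str, t_fus: float) -> str:
            fused = _star([f"{species}|fusedSD|f{i}" for i in range(1, n + 1)], t_fus)
            return f"({species}|SD1|ref:{t_fus:g},{fused}):{cfg.t_div - t_fus:g}"

        sd1_clade = f"({sp_clade(sp_a, cfg.t_fusion_a)},{sp_clade(sp_b, cfg.t_fusion_b)}):{cfg.t_pre_split:g}"
        sd2_clade = (
            f"(({sp_a}|SD2|ref:{cfg.t_div:g},{sp_b}|SD2|ref:{cfg.t_div:g})"
            f":{cfg.t_pre_split:g})"
        )
        genealogy = f"({sd1_clade},{sd2_clade});"

    else:  # ibd: one fusion t_fusion_a years before the split
        t_off = cfg.t_fusion_a
        t_star = cfg.t_ibd_star
        sd1_pre, _ = evolve_branch(root, cfg.t_pre_split - t_off, rate, rng)
        sd2_pre, _ = evolve_branch(root, cfg.t_pre_split - t_off, rate, rng)
        _apply_tracts(sd1_pre, sd2_pre, cfg.ancestral_conversion_tracts)
        founder_anc = np.concatenate([sd1_pre[:bp_a], sd2_pre[bp_a:]])
        sd1_anc, _ = evolve_branch(sd1_pre, t_off, rate, rng)   # fusion -> split
        sd2_anc, _ = evolve_branch(sd2_pre, t_off, rate, rng)
        fused_split, _ = evolve_branch(founder_anc, t_off, rate, rng)

        for species in (sp_a, sp_b):
            sd1_s = sd1_anc.copy()
            sd2_s = sd2_anc.copy()
            _apply_tracts(sd1_s, sd2_s, cfg.lineage_conversion_tracts.get(species, ()))
            sd1_ref, _ = evolve_branch(sd1_s, cfg.t_div, rate, rng)
            sd2_ref, _ = evolve_branch(sd2_s, cfg.t_div, rate, rng)
            rec(species, "SD1", "ref", sd1_ref)
            rec(species, "SD2", "ref", sd2_ref)
            star_founder, _ = evolve_branch(fused_split, cfg.t_div - t_star, rate, rng)
            for i in range(1, n + 1):
                hap, _ = evolve_branch(star_founder, t_star, rate, rng)
                rec(species, "fusedSD", f"f{i}", hap)

        def sp_star(species: str) -> str:
            fused = _star([f"{species}|fusedSD|f{i}" for i in range(1, n + 1)], t_star)
            return f"({fused}):{cfg.t_div - t_star:g}"

        fused_clade = f"({sp_star(sp_a)},{sp_star(sp_b)}):{t_off:g}"
        sd1_tip = f"({sp_a}|SD1|ref:{cfg.t_div:g},{sp_b}|SD1|ref:{cfg.t_div:g}):{t_off:g}"
        sd1_side = f"({sd1_tip},{fused_clade}):{cfg.t_pre_split - t_off:g}"
        sd2_side = (
            f"(({sp_a}|SD2|ref:{cfg.t_div:g},{sp_b}|SD2|ref:{cfg.t_div:g})"
            f":{cfg.t_pre_split:g})"
        )
        genealogy = f"({sd1_side},{sd2_side});"

    truth = SimTruth(
        scenario=cfg.scenario,
        seed=cfg.seed,
        breakpoint_a=bp_a,
        breakpoint_b=bp_b,
        ancestral_conversion_tracts=list(cfg.ancestral_conversion_tracts),
        lineage_conversion_tracts={k: list(v) for k, v in cfg.lineage_conversion_tracts.items()},
        genealogy=genealogy,
    )
    return SDAlignment(records), truth


# ---- truth file round-trip ------------------------------------------------

_TRUTH_HEADER = "# sdfusion truth v1"


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Write a SimTruth as a tab-separated text file (lossless round-trip)."""
    lines = [_TRUTH_HEADER]
    lines.append(f"scenario\t{truth.scenario}")
    lines.append(f"seed\t{truth.seed}")
    lines.append(f"breakpoint_a\t{truth.breakpoint_a}")
    lines.append(f"breakpoint_b\t{truth.breakpoint_b}")
    for s, e, d in truth.ancestral_conversion_tracts:
        lines.append(f"tract\tancestral\t{s}\t{e}\t{d}")
    for lin, tracts in sorted(truth.lineage_conversion_tracts.items()):
        for s, e, d in tracts:
            lines.append(f"tract\t{lin}\t{s}\t{e}\t{d}")
    lines.append(f"genealogy\t{truth.genealogy}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> SimTruth:
    text = Path(path).read_text().rstrip("\n").split("\n")
    if not text or text[0] != _TRUTH_HEADER:
        raise ValueError(f"{path}: not an sdfusion truth file")
    fields: dict[str, str] = {}
    anc: list[tuple[int, int, str]] = []
    lin: dict[str, list[tuple[int, int, str]]] = {}
    for line in text[1:]:
        parts = line.split("\t")
        if parts[0] == "tract":
            _, who, s, e, d = parts
            if who == "ancestral":
                anc.append((int(s), int(e), d))
            else:
                lin.setdefault(who, []).append((int(s), int(e), d))
        else:
            fields[parts[0]] = parts[1]
    return SimTruth(
        scenario=fields["scenario"],
        seed=int(fields["seed"]),
        breakpoint_a=int(fields["breakpoint_a"]),
        breakpoint_b=int(fields["breakpoint_b"]),
        ancestral_conversion_tracts=anc,
        lineage_conversion_tracts=lin,
        genealogy=fields["genealogy"],
    )
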