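"""Ready-made simulation presets for the five benchmark allopolyploidy
scenarios: a tetraploid-hexaploid complex whose third subgenome is sister
to one of the shared pair (wheat-like, [[A,D],B]), one whose third
subgenome is the outgroup of the shared pair (oat-like, [[A,D],C]), a
tetraploid-octoploid reticulation (poppy-like, [D,[C,[B,A]]]), three
tetraploids sharing diploid parents pairwise (U's-triangle-like), and a
single octoploid with two sister subgenomes (strawberry-like,
[V,[I,[T1,T2]]]).

Presets expose divergence as a per-branch substitution proportion
directly; no molecular-clock mapping from divergence times is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .io_formats import GenomeComplex
from .synthetic import (GroundTruth, SimGenome, SimulationConfig, render,
                        simulate_allopolyploid, simulate_progenitors)


@dataclass
class PresetSpec:
    name: str
    species_tree: str
    merges: list            # (species_id, [parent labels or earlier species ids])
    complex_species: list   # species analysed together (truth exists for each)


PRESETS: dict[str, PresetSpec] = {
    # AABB + AABBDD; D sister to A
    "wheat": PresetSpec("wheat", "(((A,D),B),Out);",
                        [("TT", ["A", "B"]), ("TA", ["TT", "D"])],
                        ["TT", "TA"]),
    # CCDD + AACCDD; D sister to A, C outside
    "oat": PresetSpec("oat", "(((A,D),C),Out);",
                      [("AI", ["C", "D"]), ("AS", ["AI", "A"])],
                      ["AI", "AS"]),
    # AACC + AABBCCDD via an extinct BBDD tetraploid
    "poppy": PresetSpec("poppy", "((((A,B),C),D),Out);",
                        [("PS", ["A", "C"]), ("BD", ["B", "D"]),
                         ("PX", ["PS", "BD"])],
                        ["PS", "PX"]),
    # AABB + AACC + BBCC sharing diploid parents pairwise
    "u_triangle": PresetSpec("u_triangle", "(((A,C),B),Out);",
                             [("BJ", ["A", "B"]), ("BN", ["A", "C"]),
                              ("BC", ["B", "C"])],
                             ["BJ", "BN", "BC"]),
    # single octoploid with sister subgenomes T1/T2
    "strawberry": PresetSpec("strawberry", "((((T1,T2),I),V),Out);",
                             [("F4", ["T1", "T2"]), ("F6", ["F4", "I"]),
                              ("FA", ["F6", "V"])],
                             ["FA"]),
}

# sister pairs that are only relatively phaseable within the single-complex
# consensus (equivalent phylogenetic positions)
RELATIVE_PAIRS: dict[str, list[tuple[str, str]]] = {
    "wheat": [], "oat": [], "poppy": [], "u_triangle": [],
    "strawberry": [("T1", "T2")],
}


@dataclass
class PresetBundle:
    name: str
    config: SimulationConfig
    progenitors: dict            # label -> SimGenome
    sims: dict                   # species id -> SimGenome (merged polyploids)
    complexes: dict              # species id -> GenomeComplex (study complex)
    truths: dict                 # species id -> GroundTruth
    outgroup: GenomeComplex
    outgroup_sim: SimGenome
    groups: dict = field(default_factory=dict)    # species -> list of chromosome groups
    ploidies: dict = field(default_factory=dict)  # species -> subgenome count


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def build_preset(name: str, seed: int = 0, config: SimulationConfig | None = None,
                 ) -> PresetBundle:
    """Simulate a full study complex for one preset scenario.

    Every species in the complex is rendered with its ground truth; the
    homoeologous-chromosome grouping (known by construction) is included,
    mirroring the grouping a synteny pre-analysis would supply.
    """
    spec = PRESETS[name]
    cfg = config or SimulationConfig()
    cfg = replace(cfg, seed=seed, species_tree=spec.species_tree)
    progenitors, outgroup_sim = simulate_progenitors(cfg)
    sims: dict[str, SimGenome] = dict(progenitors)
    for i, (sid, parents) in enumerate(spec.merges):
        sims[sid] = simulate_allopolyploid(
            [sims[p] for p in parents], species_id=sid,
            fractionation_rate=cfg.fractionation_rate,
            seed=(cfg.seed * 9973 + 31 * i + 7) % (2 ** 31),
            extra_divergence=cfg.polyploid_divergence)
    complexes, truths, groups, ploidies = {}, {}, {}, {}
    for sid in spec.complex_species:
        gc, truth = render(sims[sid], cfg.species_tree)
        complexes[sid] = gc
        truths[sid] = truth
        by_group: dict[str, list[str]] = {}
        for chrom in sims[sid].chromosomes:
            by_group.setdefault(chrom.group, []).append(chrom.name)
        groups[sid] = [sorted(v) for _, v in sorted(by_group.items())]
        ploidies[sid] = max(len(v) for v in groups[sid]) if groups[sid] else 0
    outgroup_gc, _ = render(outgroup_sim, cfg.species_tree)
    return PresetBundle(name=name, config=cfg, progenitors=progenitors,
                        sims=sims, complexes=complexes, truths=truths,
                        outgroup=outgroup_gc, outgroup_sim=outgroup_sim,
                        groups=groups, ploidies=ploidies)


def expected_column_topology(name: str, complex_species: list[str] | None = None,
                             outgroup_tip: str = "OUTGROUP") -> str:
    """The generating topology over (species|subgenome) columns: the
    species tree with every progenitor leaf expanded into the clade of the
    complex species carrying it."""
    spec = PRESETS[name]
    species = complex_species or spec.complex_species
    # subgenome content per species, by replaying the merges symbolically
    content: dict[str, list[str]] = {}
    diploids = set()
    for sid, parents in spec.merges:
        subs: list[str] = []
        for p in parents:
            if p in content:
                subs.extend(content[p])
            else:
                subs.append(p)
                diploids.add(p)
        content[sid] = subs
    carriers: dict[str, list[str]] = {}
    for sid in species:
        for sub in content[sid]:
            carriers.setdefault(sub, []).append(sid)

    def expand(token: str) -> str:
        token = token.strip()
        if token.startswith("("):
            depth = 0
            parts, cur = [], ""
            for ch in token[1:-1]:
                if ch == "(":
                    depth += 1
                elif ch == ")":
                    depth -= 1
                if ch == "," and depth == 0:
                    parts.append(cur)
                    cur = ""
                else:
                    cur += ch
            parts.append(cur)
            return "(" + ",".join(expand(p) for p in parts) + ")"
        if token == "Out":
            return outgroup_tip
        cols = [f"{sid}|{token}" for sid in carriers.get(token, [])]
        if not cols:
            return token
        if len(cols) == 1:
            return cols[0]
        return "(" + ",".join(sorted(cols)) + ")"

    tree = spec.species_tree.rstrip(";").strip()
    return expand(tree) + ";"
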