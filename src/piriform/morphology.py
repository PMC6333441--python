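"""Dendritic morphology: synthetic generation, SWC I/O, discretization and queries.

The model cell is an apical dendritic tree of cylindrical sections rooted at
an isopotential soma.  Several primary (root) dendrites leave the soma and
branch into terminal tufts; the distal portion of the tree receives lateral
olfactory tract (LOT) afferents while more proximal apical segments receive
intracortical (IC) input.  The generator emulates the summary statistics of
reconstructed piriform-cortex layer-II/III pyramidal cells: soma membrane
area 829 µm², total dendritic length within 2238–2516 µm, and a spatial
extent that reaches beyond 350 µm from the soma so that distal LOT
stimulation sites exist.

All lengths and diameters are in micrometres.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "Compartment",
    "CompartmentGrid",
    "DendriticLocation",
    "GeneratorParams",
    "MorphologyError",
    "SWCError",
    "generate_synthetic_morphology",
    "discretize",
    "read_swc",
    "write_swc",
    "path_distance",
    "classify_zone",
    "branch_relation",
    "morphology_summary",
]

#: soma modelled as a cylinder with length == diameter; lateral area pi*L*d
DEFAULT_SOMA_AREA = 829.0  # µm²

#: printed range of total apical dendritic length of the reconstructed cells
DEFAULT_TOTAL_LENGTH_RANGE = (2238.0, 2516.0)  # µm

#: default spatial discretization; 19 µm is the hard cap, the mean
#: compartment length implied by the printed compartment counts is ~4.6 µm
DEFAULT_MAX_SEG_LEN = 4.6
HARD_MAX_SEG_LEN = 19.0

DEFAULT_LOT_BAND_START = 250.0  # µm path distance where the LOT band begins
PERISOMATIC_LIMIT = 100.0  # µm


class MorphologyError(ValueError):
    """Violated structural or generator constraint."""


class SWCError(ValueError):
    """Malformed SWC content."""


@dataclass(frozen=True)
class Section:
    """A cylindrical (tapering) dendritic section.

    ``parent`` is the index of the parent section in ``Morphology.sections``
    or ``-1`` when the section attaches directly to the soma.
    """

    index: int
    parent: int
    length: float
    diam_prox: float
    diam_dist: float
    branch_order: int
    root_id: int  # which primary dendrite off the soma this descends from

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise MorphologyError(f"section {self.index}: length must be > 0")
        if self.diam_prox <= 0 or self.diam_dist <= 0:
            raise MorphologyError(f"section {self.index}: diameters must be > 0")


@dataclass(frozen=True)
class Morphology:
    sections: tuple[Section, ...]
    soma_area: float  # µm²

    def __post_init__(self) -> None:
        if self.soma_area <= 0:
            raise MorphologyError("soma area must be > 0")
        seen: set[int] = set()
        for i, sec in enumerate(self.sections):
            if sec.index != i:
                raise MorphologyError("section indices must be 0..n-1 in order")
            if sec.parent >= i:
                raise MorphologyError(
                    f"section {i}: parent must precede child (acyclic tree)"
                )
            if sec.parent >= 0 and sec.parent not in seen:
                raise MorphologyError(f"section {i}: unknown parent {sec.parent}")
            seen.add(i)

    @property
    def total_length(self) -> float:
        return float(sum(s.length for s in self.sections))

    @property
    def soma_diameter(self) -> float:
        """Diameter of the equivalent soma cylinder with length == diameter."""
        return math.sqrt(self.soma_area / math.pi)

    def children(self, index: int) -> list[int]:
        return [s.index for s in self.sections if s.parent == index]

    def terminal_sections(self) -> list[int]:
        has_child = {s.parent for s in self.sections}
        return [s.index for s in self.sections if s.index not in has_child]

    def section_path_start(self, index: int) -> float:
        """Path distance (µm) from the soma to the proximal end of a section."""
        d = 0.0
        parent = self.sections[index].parent
        while parent >= 0:
            d += self.sections[parent].length
            parent = self.sections[parent].parent
        return d

    def n_primary(self) -> int:
        return sum(1 for s in self.sections if s.parent == -1)


@dataclass(frozen=True)
class DendriticLocation:
    """A point on the tree: section index plus normalized arc position (0–1)."""

    section: int
    arc: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.arc <= 1.0:
            raise MorphologyError("arc position must lie in [0, 1]")


@dataclass(frozen=True)
class Compartment:
    section: int  # -1 for the soma compartment
    arc_mid: float  # arc position of compartment midpoint within its section
    length: float  # µm
    diameter: float  # µm at midpoint
    area: float  # µm² membrane area
    path_distance: float  # µm from soma to compartment midpoint


@dataclass(frozen=True)
class CompartmentGrid:
    """Spatially discretized morphology.

    ``parent_comp[i]`` is the compartment electrically upstream of ``i``
    (towards the soma); compartment 0 is the soma and has parent ``-1``.
    ``section_offset`` maps a section index to the index of its first
    compartment; ``section_ncomp`` gives the number of compartments per
    section.
    """

    morphology: Morphology
    compartments: tuple[Compartment, ...]
    parent_comp: tuple[int, ...]
    section_offset: tuple[int, ...]
    section_ncomp: tuple[int, ...]
    max_seg_len: float

    @property
    def n_comp(self) -> int:
        return len(self.compartments)

    def comp_index(self, loc: DendriticLocation) -> int:
        """Compartment containing a dendritic location."""
        self._check_section(loc.section)
        n = self.section_ncomp[loc.section]
        k = min(int(loc.arc * n), n - 1)
        return self.section_offset[loc.section] + k

    def _check_section(self, section: int) -> None:
        if not 0 <= section < len(self.section_offset):
            raise KeyError(f"unknown section index {section}")


# ---------------------------------------------------------------------------
# synthetic morphology generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic-tree generator.

    The reconstructed cells' branch-order statistics and diameters were not
    published; the tree shape here is a configurable stand-in constrained by
    the printed summary statistics (soma area, total length, spatial extent).
    Each primary dendrite is a balanced tuft — a trunk bifurcating into
    branches whose every root-to-tip path reaches the primary's tip extent —
    so that same/sister/different-branch comparisons see matched geometry.
    Section lengths are solved from the per-primary length budget, jittered
    in a compensating way, and the whole tree is nudged into
    ``total_length_range``.
    """

    n_primary: int = 3
    soma_area: float = DEFAULT_SOMA_AREA
    total_length_range: tuple[float, float] = DEFAULT_TOTAL_LENGTH_RANGE
    min_path_extent: float = 350.0  # µm; distal LOT sites must exist
    #: every primary dendrite reaches at least this far, so LOT-band sites
    #: of comparable geometry exist on sister and different branches alike
    min_primary_extent: float = 340.0
    #: extra reach (µm) above the minimum extent; tip distances are drawn
    #: uniformly from [min extent, min extent + extent_jitter]
    extent_jitter: float = 20.0
    #: children per branch level below the trunk; (2, 2) gives a trunk, two
    #: children and four terminal tuft branches per primary dendrite
    branching: tuple[int, ...] = (2, 2)
    #: relative extent fraction of each non-terminal level (trunk first);
    #: the absolute fractions are solved from the length budget so that every
    #: root-to-tip path reaches the primary's tip extent (a balanced tuft)
    level_shape: tuple[float, ...] = (1.0, 0.6)
    length_jitter: float = 0.10  # fractional jitter applied within levels
    #: diameter by branch order (taper), terminal order clamps to the last.
    #: A stout proximal backbone keeps somatic transfer high (so the unitary
    #: calibration needs only moderate conductance) while the thin terminal
    #: tuft branches give the high local impedance NMDA spikes need — a
    #: single calibrated input stays subthreshold, a clustered group does not
    diam_by_order: tuple[float, ...] = (3.0, 2.2, 1.5)


def generate_synthetic_morphology(
    params: GeneratorParams | None = None, seed: int = 0
) -> Morphology:
    """Generate a random apical tree satisfying the structural invariants.

    Deterministic for a fixed seed.  Raises :class:`MorphologyError` when the
    constraints cannot be met (e.g. the target length range is too short to
    reach ``min_path_extent``).
    """
    p = params or GeneratorParams()
    if p.n_primary < 2:
        raise MorphologyError(
            "n_primary must be >= 2 so sister/different branch relations exist"
        )
    lo, hi = p.total_length_range
    if not 0 < lo <= hi:
        raise MorphologyError("total_length_range must be positive and ordered")
    if p.min_primary_extent > p.min_path_extent:
        raise MorphologyError("min_primary_extent must be <= min_path_extent")
    if len(p.level_shape) != len(p.branching):
        raise MorphologyError("level_shape must have one entry per branching level")
    if any(b < 1 for b in p.branching) or any(w <= 0 for w in p.level_shape):
        raise MorphologyError("branching factors and level shape must be positive")

    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    total = float(rng.uniform(lo, hi))

    # local node topology of one primary: BFS order, trunk first
    node_parent: list[int] = [-1]
    node_level: list[int] = [0]
    frontier = [0]
    for lvl, nchild in enumerate(p.branching, start=1):
        nxt = []
        for par in frontier:
            for _ in range(nchild):
                node_parent.append(par)
                node_level.append(lvl)
                nxt.append(len(node_parent) - 1)
        frontier = nxt
    n_nodes = len(node_parent)
    n_levels = len(p.branching)  # non-terminal levels: 0..n_levels-1
    tips = [i for i in range(n_nodes) if node_level[i] == n_levels]
    n_tips = len(tips)
    # sections per non-terminal level
    n_at = [sum(1 for l in node_level if l == lvl) for lvl in range(n_levels)]

    # per-primary budgets (near-equal) and tip extents
    w = rng.dirichlet(np.full(p.n_primary, 400.0))
    budgets = total * w
    # small margin keeps tips above the required extents after the final
    # total-length adjustment
    margin = 8.0
    extents = np.empty(p.n_primary)
    extents[0] = rng.uniform(
        p.min_path_extent + margin, p.min_path_extent + margin + p.extent_jitter
    )
    for i in range(1, p.n_primary):
        extents[i] = rng.uniform(
            p.min_primary_extent + margin,
            p.min_primary_extent + margin + p.extent_jitter,
        )

    def diam(order: int) -> float:
        return p.diam_by_order[min(order, len(p.diam_by_order) - 1)]

    sections: list[Section] = []
    for root in range(p.n_primary):
        b, e = float(budgets[root]), float(extents[root])
        # solve the absolute extent fraction of each non-terminal level so
        # that a balanced tuft (every tip at extent e) consumes budget b:
        #   b/e = n_tips - sum_l (n_tips - n_at[l]) * lambda_l,
        # with lambda_l = alpha * shape_l
        denom = sum(
            (n_tips - n_at[lvl]) * p.level_shape[lvl] for lvl in range(n_levels)
        )
        alpha = (n_tips - b / e) / denom
        lam = [alpha * p.level_shape[lvl] for lvl in range(n_levels)]
        term_frac = 1.0 - sum(lam)
        if alpha <= 0.0 or term_frac * e < 15.0 or any(l * e < 5.0 for l in lam):
            raise MorphologyError(
                f"balanced tuft unsolvable: primary budget {b:.0f} µm vs tip "
                f"extent {e:.0f} µm leaves no room for terminal branches"
            )

        # jitter sibling groups in a compensating way: section lengths within
        # a sibling group vary but each root-to-tip path still sums to e,
        # because every terminal absorbs its own path's remainder
        lengths = np.empty(n_nodes)
        depth_to = np.empty(n_nodes)  # path length soma -> distal end of node
        for i in range(n_nodes):
            lvl = node_level[i]
            if lvl < n_levels:
                jit = 1.0 + p.length_jitter * float(rng.uniform(-1.0, 1.0))
                lengths[i] = lam[lvl] * e * jit
            else:
                lengths[i] = e - depth_to[node_parent[i]]
                if lengths[i] < 5.0:
                    raise MorphologyError(
                        "length jitter leaves a terminal shorter than 5 µm"
                    )
            start = depth_to[node_parent[i]] if node_parent[i] >= 0 else 0.0
            depth_to[i] = start + lengths[i]

        base = len(sections)
        for i in range(n_nodes):
            lvl = node_level[i]
            parent = -1 if node_parent[i] == -1 else base + node_parent[i]
            sections.append(
                Section(
                    base + i,
                    parent,
                    float(lengths[i]),
                    diam(lvl),
                    diam(lvl + 1),
                    lvl,
                    root,
                )
            )

    morph = Morphology(tuple(sections), soma_area=p.soma_area)
    # the compensating jitter shifts the realized total slightly; rescale
    # uniformly only when it leaves the configured range (tips move by at
    # most the same small factor, which the extent margin absorbs)
    realized = morph.total_length
    factor = 1.0
    if realized < lo:
        factor = lo / realized
    elif realized > hi:
        factor = hi / realized
    if abs(factor - 1.0) > 1e-12:
        sections = [
            Section(
                s2.index, s2.parent, s2.length * factor, s2.diam_prox,
                s2.diam_dist, s2.branch_order, s2.root_id,
            )
            for s2 in sections
        ]
        morph = Morphology(tuple(sections), soma_area=p.soma_area)
    _validate_generated(morph, p)
    return morph


def _validate_generated(morph: Morphology, p: GeneratorParams) -> None:
    lo, hi = p.total_length_range
    tot = morph.total_length
    if not lo - 1e-6 <= tot <= hi + 1e-6:
        raise MorphologyError(
            f"generated total length {tot:.1f} µm outside [{lo}, {hi}]"
        )
    extent = max(
        morph.section_path_start(t) + morph.sections[t].length
        for t in morph.terminal_sections()
    )
    if extent < p.min_path_extent - 1e-6:
        raise MorphologyError(
            f"maximum path distance {extent:.1f} µm < required {p.min_path_extent}"
        )


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


def discretize(morph: Morphology, max_seg_len: float = DEFAULT_MAX_SEG_LEN) -> CompartmentGrid:
    """Subdivide every section into compartments of length <= ``max_seg_len``.

    The number of compartments per section is ``ceil(length / max_seg_len)``
    and compartments within a section share a common length, so the sum of
    compartment lengths always equals the section length.  Compartment 0 is
    the soma.
    """
    if max_seg_len <= 0:
        raise ValueError("max_seg_len must be > 0")

    soma_d = morph.soma_diameter
    comps: list[Compartment] = [
        Compartment(-1, 0.5, soma_d, soma_d, morph.soma_area, 0.0)
    ]
    parent_comp: list[int] = [-1]
    offsets: list[int] = []
    ncomps: list[int] = []

    sec_last_comp: dict[int, int] = {}
    for sec in morph.sections:
        n = max(1, math.ceil(sec.length / max_seg_len - 1e-12))
        seg_len = sec.length / n
        offsets.append(len(comps))
        ncomps.append(n)
        start = morph.section_path_start(sec.index)
        up = sec_last_comp[sec.parent] if sec.parent >= 0 else 0
        for k in range(n):
            arc_mid = (k + 0.5) / n
            d = sec.diam_prox + (sec.diam_dist - sec.diam_prox) * arc_mid
            comps.append(
                Compartment(
                    section=sec.index,
                    arc_mid=arc_mid,
                    length=seg_len,
                    diameter=d,
                    area=math.pi * d * seg_len,
                    path_distance=start + (k + 0.5) * seg_len,
                )
            )
            parent_comp.append(up)
            up = len(comps) - 1
        sec_last_comp[sec.index] = up

    return CompartmentGrid(
        morphology=morph,
        compartments=tuple(comps),
        parent_comp=tuple(parent_comp),
        section_offset=tuple(offsets),
        section_ncomp=tuple(ncomps),
        max_seg_len=float(max_seg_len),
    )


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------


def path_distance(grid: CompartmentGrid, loc: DendriticLocation) -> float:
    """Path distance (µm) from the soma to a dendritic location."""
    grid._check_section(loc.section)
    morph = grid.morphology
    sec = morph.sections[loc.section]
    return morph.section_path_start(loc.section) + loc.arc * sec.length


def classify_zone(
    grid: CompartmentGrid,
    loc: DendriticLocation,
    lot_band_start: float = DEFAULT_LOT_BAND_START,
    perisomatic_limit: float = PERISOMATIC_LIMIT,
) -> str:
    """Classify a location as ``'perisomatic'``, ``'IC'`` or ``'LOT'``.

    The apical tree of a piriform-cortex pyramidal cell is laminated: distal
    segments (layer 1a) receive LOT afferents, intermediate segments receive
    intracortical (IC) input, and the region within 100 µm of the soma is
    perisomatic.  The LOT band onset is configurable; 250 µm matches the
    distal stimulation sites the protocols use.
    """
    d = path_distance(grid, loc)
    if d <= perisomatic_limit:
        return "perisomatic"
    if d >= lot_band_start:
        return "LOT"
    return "IC"


def branch_relation(
    morph: Morphology, loc_a: DendriticLocation, loc_b: DendriticLocation
) -> str:
    """Relation between two dendritic locations: same / sister / different.

    ``same``: the locations lie on one section or on sections along a single
    unbranched root-to-tip path (one is an ancestor of the other with no
    intervening bifurcation separating them onto distinct subtrees).
    ``sister``: distinct branches that descend from the same primary (root)
    dendrite off the soma.  ``different``: branches of two distinct primary
    dendrites.
    """
    sa, sb = loc_a.section, loc_b.section
    for s in (sa, sb):
        if not 0 <= s < len(morph.sections):
            raise KeyError(f"unknown section index {s}")
    if sa == sb:
        return "same"

    def ancestors(i: int) -> list[int]:
        out = [i]
        while morph.sections[i].parent >= 0:
            i = morph.sections[i].parent
            out.append(i)
        return out

    anc_a, anc_b = ancestors(sa), ancestors(sb)
    if sa in anc_b or sb in anc_a:
        return "same"
    if morph.sections[sa].root_id == morph.sections[sb].root_id:
        return "sister"
    return "different"


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

_SWC_SOMA = 1
_SWC_APICAL = 4


def write_swc(morph: Morphology, path: str) -> None:
    """Write the morphology as standard 7-column SWC.

    The soma is written as a single sample whose sphere area equals the soma
    membrane area.  The synthetic tree carries no 3D embedding, so a planar
    layout is synthesized: each primary dendrite leaves the soma at an evenly
    spaced angle and children deviate ±35° from their parent's direction.
    Geometry (section lengths, diameters, topology) is preserved exactly.
    """
    soma_r = math.sqrt(morph.soma_area / (4.0 * math.pi))
    lines = [
        "# SWC export: piriform-cortex pyramidal cell model (synthetic layout)",
        f"1 {_SWC_SOMA} 0.0 0.0 0.0 {soma_r:.6f} -1",
    ]
    next_id = 2
    # per-section: (last sample id, direction angle, end x, end y)
    state: dict[int, tuple[int, float, float, float]] = {}
    n_primary = morph.n_primary()
    prim_seen = 0
    for sec in morph.sections:
        if sec.parent == -1:
            angle = 2.0 * math.pi * prim_seen / max(n_primary, 1)
            prim_seen += 1
            pid, x0, y0 = 1, 0.0, 0.0
        else:
            pid, pangle, x0, y0 = state[sec.parent]
            siblings = morph.children(sec.parent)
            k = siblings.index(sec.index)
            angle = pangle + math.radians(35.0) * (1 if k % 2 == 0 else -1) / (
                1 + k // 2
            )
        # two samples per section (proximal, distal) preserve the taper
        n_pts = 2
        ids = []
        for j in range(1, n_pts + 1):
            frac = j / n_pts
            x = x0 + sec.length * frac * math.cos(angle)
            y = y0 + sec.length * frac * math.sin(angle)
            d = sec.diam_prox + (sec.diam_dist - sec.diam_prox) * frac
            lines.append(
                f"{next_id} {_SWC_APICAL} {x:.6f} {y:.6f} 0.0 {d / 2.0:.6f} {pid}"
            )
            ids.append(next_id)
            pid = next_id
            next_id += 1
        end_x = x0 + sec.length * math.cos(angle)
        end_y = y0 + sec.length * math.sin(angle)
        state[sec.index] = (ids[-1], angle, end_x, end_y)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_swc(path: str) -> Morphology:
    """Read a standard 7-column SWC file into a :class:`Morphology`.

    Soma samples (type 1) are collapsed to a single membrane area (sphere
    area of the first soma sample).  Chains of dendritic samples between
    branch points become sections; section length is the summed euclidean
    distance along the chain and diameters are taken at its ends.
    """
    records: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                sid = int(parts[0])
                stype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCError(f"line {lineno}: {exc}") from None
            if r <= 0:
                raise SWCError(f"line {lineno}: radius must be > 0")
            if sid in records:
                raise SWCError(f"line {lineno}: duplicate sample id {sid}")
            records[sid] = (stype, x, y, z, r, parent)

    if not records:
        raise SWCError("empty SWC file")

    for sid, (_, _, _, _, _, parent) in records.items():
        if parent != -1 and parent not in records:
            raise SWCError(f"sample {sid} references missing parent {parent}")
    # cycle check: walk each sample to a root
    for sid in records:
        seen = set()
        cur = sid
        while cur != -1:
            if cur in seen:
                raise SWCError(f"cyclic parent links involving sample {sid}")
            seen.add(cur)
            cur = records[cur][5]

    soma_ids = [sid for sid, rec in records.items() if rec[0] == _SWC_SOMA]
    if not soma_ids:
        raise SWCError("no soma (type 1) sample found")
    soma_root = min(soma_ids)
    soma_r = records[soma_root][4]
    soma_area = 4.0 * math.pi * soma_r**2

    children: dict[int, list[int]] = {}
    for sid, rec in sorted(records.items()):
        children.setdefault(rec[5], []).append(sid)

    def is_soma(sid: int) -> bool:
        return records[sid][0] == _SWC_SOMA

    def dist(a: int, b: int) -> float:
        _, xa, ya, za, _, _ = records[a]
        _, xb, yb, zb, _, _ = records[b]
        return math.dist((xa, ya, za), (xb, yb, zb))

    sections: list[Section] = []
    sec_of_chain_end: dict[int, int] = {}

    # section starts: dendritic samples whose parent is soma or a branch point
    def walk(start: int, parent_sec: int, root_id: int, order: int) -> None:
        chain = [start]
        cur = start
        while True:
            kids = [k for k in children.get(cur, []) if not is_soma(k)]
            if len(kids) == 1:
                chain.append(kids[0])
                cur = kids[0]
            else:
                break
        # length along the chain, anchored at the parent sample (the leg from
        # the soma sample to the first dendritic sample belongs to the section)
        p = records[start][5]
        pts = ([p] if p != -1 else []) + chain
        length = sum(dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1))
        if length <= 0:
            length = max(dist(chain[0], chain[-1]), 1e-3)
        d_prox = 2.0 * records[chain[0]][4]
        d_dist = 2.0 * records[chain[-1]][4]
        idx = len(sections)
        rid = root_id if root_id >= 0 else idx
        sections.append(Section(idx, parent_sec, length, d_prox, d_dist, order, rid))
        sec_of_chain_end[cur] = idx
        for k in [k for k in children.get(cur, []) if not is_soma(k)]:
            walk(k, idx, rid, order + 1)

    for sid in sorted(records):
        rec = records[sid]
        if is_soma(sid):
            continue
        parent = rec[5]
        if parent == -1 or is_soma(parent):
            walk(sid, -1, -1, 0)

    return Morphology(tuple(sections), soma_area=soma_area)


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------


def morphology_summary(
    grid: CompartmentGrid, lot_band_start: float = DEFAULT_LOT_BAND_START
) -> dict:
    """JSON-serializable summary: lengths, compartment count, zone breakdown."""
    morph = grid.morphology
    zone_len = {"perisomatic": 0.0, "IC": 0.0, "LOT": 0.0}
    for i, c in enumerate(grid.compartments):
        if c.section < 0:
            continue
        loc = DendriticLocation(c.section, c.arc_mid)
        zone_len[classify_zone(grid, loc, lot_band_start)] += c.length
    return {
        "soma_area_um2": morph.soma_area,
        "total_dendritic_length_um": morph.total_length,
        "n_sections": len(morph.sections),
        "n_compartments": grid.n_comp,
        "n_primary_dendrites": morph.n_primary(),
        "max_path_distance_um": max(
            c.path_distance + c.length / 2 for c in grid.compartments
        ),
        "zone_length_um": zone_len,
    }


def summary_to_json(grid: CompartmentGrid, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(morphology_summary(grid), fh, indent=2)
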