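"""Simulation box and species-tagged confinement domains.

The membrane patch is a periodic rectangle of area 0.1995 um^2 containing
5 ErbB2-specific and 9 ErbB3-specific transient-confinement domains
(total areas 0.0502 and 0.0274 um^2).  Domains of the same species never
overlap; cross-species overlap is the controlled variable of the study.
The published domain maps are irregular shapes derived from single
particle tracking and are not available as coordinates, so fixture
landscapes emulate them with axis-aligned rectangles: total areas and the
ErbB3-into-ErbB2 overlap fraction are honoured, the shapes are not.

Membership is half-open (closed on the lower edges, open on the upper
edges) so that a point on a shared edge belongs to exactly one side.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import box as shapely_box
from shapely.ops import unary_union

from .parameters import SPECIES

#: area of the simulation space, um^2
BOX_AREA = 0.1995
#: side of the (square) default box, um
BOX_SIDE = math.sqrt(BOX_AREA)

N_DOMAINS = {"ErbB2": 5, "ErbB3": 9}
TOTAL_DOMAIN_AREA = {"ErbB2": 0.0502, "ErbB3": 0.0274}

#: overlap fraction echoing the published CHO-cell map (statistical only)
CHO_LIKE_OVERLAP = 0.424


@dataclass(frozen=True)
class Domain:
    """Axis-aligned rectangular confinement domain tagged with the species
    it confines."""

    species: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("domain must have positive area")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x: float, y: float) -> bool:
        """Half-open membership: lower edges included, upper excluded."""
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max

    def as_polygon(self):
        return shapely_box(self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class Landscape:
    """Rectangular periodic box plus a set of confinement domains."""

    width: float = BOX_SIDE
    height: float = BOX_SIDE
    domains: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("box dimensions must be positive")
        self.validate()

    # -- derived geometry --------------------------------------------------

    @property
    def box_area(self) -> float:
        return self.width * self.height

    def domains_of(self, species: str) -> tuple:
        return tuple(d for d in self.domains if d.species == species)

    def _union(self, species: str):
        doms = self.domains_of(species)
        return unary_union([d.as_polygon() for d in doms]) if doms else None

    def total_domain_area(self, species: str) -> float:
        u = self._union(species)
        return 0.0 if u is None else u.area

    @property
    def free_area(self) -> float:
        """Box area outside every domain."""
        polys = [d.as_polygon() for d in self.domains]
        occupied = unary_union(polys).area if polys else 0.0
        return self.box_area - occupied

    def overlap_fraction(self) -> float:
        """Fraction of the ErbB3 domain area lying inside ErbB2 domains."""
        u3 = self._union("ErbB3")
        if u3 is None or u3.area == 0.0:
            raise ValueError(
                "overlap fraction undefined: landscape has no ErbB3 domain area"
            )
        u2 = self._union("ErbB2")
        if u2 is None:
            return 0.0
        return u3.intersection(u2).area / u3.area

    # -- queries -----------------------------------------------------------

    def locate(self, x: float, y: float) -> tuple:
        """All domains containing the point (half-open membership)."""
        if not (0.0 <= x <= self.width and 0.0 <= y <= self.height):
            raise ValueError(
                f"point ({x}, {y}) outside the {self.width} x {self.height} box"
            )
        return tuple(d for d in self.domains if d.contains(x, y))

    def rect_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(m, 4) rectangle array [x_min, y_min, x_max, y_max] and the
        (m,) species-code array (0 = ErbB2, 1 = ErbB3) for the kernels."""
        m = len(self.domains)
        rects = np.zeros((m, 4))
        codes = np.zeros(m, dtype=np.int64)
        for i, d in enumerate(self.domains):
            rects[i] = (d.x_min, d.y_min, d.x_max, d.y_max)
            codes[i] = SPECIES.index(d.species)
        return rects, codes

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        for d in self.domains:
            if d.x_min < 0 or d.y_min < 0 or d.x_max > self.width or d.y_max > self.height:
                raise ValueError(f"domain {d} extends outside the box")
        for sp in SPECIES:
            doms = self.domains_of(sp)
            for i in range(len(doms)):
                for j in range(i + 1, len(doms)):
                    inter = doms[i].as_polygon().intersection(doms[j].as_polygon())
                    if inter.area > 1e-12:
                        raise ValueError(
                            f"{sp} domains {i} and {j} overlap; same-species "
                            "domains must be disjoint"
                        )

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path | None = None) -> str:
        """One domain per row: species, x_min, y_min, x_max, y_max, with a
        box-header comment line."""
        buf = io.StringIO()
        buf.write(f"# box\t{float(self.width)!r}\t{float(self.height)!r}\n")
        buf.write("species\tx_min\ty_min\tx_max\ty_max\n")
        for d in self.domains:
            buf.write(
                f"{d.species}\t{float(d.x_min)!r}\t{float(d.y_min)!r}"
                f"\t{float(d.x_max)!r}\t{float(d.y_max)!r}\n"
            )
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, source: str | Path) -> "Landscape":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("# box"):
            raise ValueError("landscape file must start with a '# box' header")
        _, w, h = lines[0].split("\t")[0], *lines[0].split("\t")[1:3]
        domains = []
        for ln in lines[2:]:
            sp, x0, y0, x1, y1 = ln.split("\t")
            domains.append(Domain(sp, float(x0), float(y0), float(x1), float(y1)))
        return cls(float(w), float(h), tuple(domains))


def build_empty_landscape() -> Landscape:
    """Domain-free box (the 'no domain' configuration)."""
    return Landscape(BOX_SIDE, BOX_SIDE, ())


def overlap_fraction(landscape: Landscape) -> float:
    """Module-level convenience wrapper for :meth:`Landscape.overlap_fraction`."""
    return landscape.overlap_fraction()


def _split_total(rng, total: float, n: int, spread: float) -> np.ndarray:
    """n positive areas with the exact ``total``, multiplicative spread
    ``1 +- spread`` around the mean."""
    m = 1.0 + rng.uniform(-spread, spread, n)
    return total * m / m.sum()


def _rect_dims(rng, area: float, max_aspect: float = 1.5) -> tuple[float, float]:
    a = rng.uniform(1.0 / max_aspect, max_aspect)
    w = math.sqrt(area * a)
    return w, area / w


def build_fixture_landscape(
    target_overlap: float,
    seed: int,
    *,
    box_side: float = BOX_SIDE,
    max_attempts: int = 64,
) -> Landscape:
    """Randomised fixture landscape with a controlled ErbB3-into-ErbB2
    overlap fraction.

    5 ErbB2 domains totalling 0.0502 um^2 and 9 ErbB3 domains totalling
    0.0274 um^2 are placed in the box.  For ``target_overlap`` strictly
    between 0 and 1, each ErbB3 domain straddles the edge of one host
    ErbB2 domain with exactly the target fraction of its area inside, so
    the achieved overlap equals the target; 0 places the two species
    disjointly and 1 nests every ErbB3 domain inside an ErbB2 domain.
    Same-species domains are always pairwise disjoint.  Geometry is a
    deterministic function of ``seed``.
    """
    if not 0.0 <= target_overlap <= 1.0:
        raise ValueError("target_overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    f = float(target_overlap)
    margin = 1e-4  # keep domains strictly inside the box

    for attempt in range(max_attempts):
        spread = 0.25 if attempt < max_attempts // 2 else 0.1
        areas2 = _split_total(rng, TOTAL_DOMAIN_AREA["ErbB2"], N_DOMAINS["ErbB2"], spread)
        areas3 = _split_total(rng, TOTAL_DOMAIN_AREA["ErbB3"], N_DOMAINS["ErbB3"], spread)
        areas2 = np.sort(areas2)[::-1]
        areas3 = np.sort(areas3)[::-1]

        hosts: list[tuple[float, float, float, float]] = []
        ok = True
        for area in areas2:
            w, h = _rect_dims(rng, area)
            placed = False
            for _ in range(600):
                x0 = rng.uniform(margin, box_side - w - margin)
                y0 = rng.uniform(margin, box_side - h - margin)
                cand = (x0, y0, x0 + w, y0 + h)
                if all(not _rects_touch(cand, other, gap=0.004) for other in hosts):
                    hosts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue

        if f >= 1.0:
            guests = _place_nested(rng, hosts, areas3, margin)
        elif f <= 0.0:
            guests = _place_disjoint(rng, hosts, areas3, box_side, margin)
        else:
            guests = _place_straddling(rng, hosts, areas3, f, box_side, margin)
        if guests is None:
            continue

        domains = tuple(
            [Domain("ErbB2", *r) for r in hosts] + [Domain("ErbB3", *r) for r in guests]
        )
        ls = Landscape(box_side, box_side, domains)
        achieved = ls.overlap_fraction()
        if abs(achieved - f) <= 0.02:
            return ls

    raise RuntimeError(
        f"could not place the fixture domains for overlap {target_overlap} with "
        f"seed {seed} after {max_attempts} attempts; try another seed or smaller "
        "domain areas"
    )


def _rects_touch(a, b, gap: float = 0.0) -> bool:
    return not (
        a[2] + gap <= b[0] or b[2] + gap <= a[0] or a[3] + gap <= b[1] or b[3] + gap <= a[1]
    )


def _place_disjoint(rng, hosts, areas3, box_side, margin):
    """ErbB3 domains intersecting neither the ErbB2 domains nor each other."""
    guests: list[tuple[float, float, float, float]] = []
    for area in areas3:
        w, h = _rect_dims(rng, area)
        for _ in range(600):
            x0 = rng.uniform(margin, box_side - w - margin)
            y0 = rng.uniform(margin, box_side - h - margin)
            cand = (x0, y0, x0 + w, y0 + h)
            if any(_rects_touch(cand, r, gap=1e-4) for r in hosts):
                continue
            if any(_rects_touch(cand, r, gap=1e-4) for r in guests):
                continue
            guests.append(cand)
            break
        else:
            return None
    return guests


def _place_nested(rng, hosts, areas3, margin):
    """Each ErbB3 domain entirely inside one ErbB2 host (100% overlap)."""
    guests: list[tuple[float, float, float, float]] = []
    for area in areas3:
        placed = False
        order = rng.permutation(len(hosts))
        for hi in order:
            hx0, hy0, hx1, hy1 = hosts[hi]
            hw, hh = hx1 - hx0, hy1 - hy0
            for _ in range(300):
                w, h = _rect_dims(rng, area)
                if w >= hw or h >= hh:
                    continue
                x0 = rng.uniform(hx0, hx1 - w)
                y0 = rng.uniform(hy0, hy1 - h)
                cand = (x0, y0, x0 + w, y0 + h)
                if any(_rects_touch(cand, g) for g in guests):
                    continue
                guests.append(cand)
                placed = True
                break
            if placed:
                break
        if not placed:
            return None
    return guests


def _place_straddling(rng, hosts, areas3, f, box_side, margin):
    """Each ErbB3 domain straddles one edge of a host ErbB2 domain with
    exactly fraction ``f`` of its area inside the host."""
    guests: list[tuple[float, float, float, float]] = []
    for area in areas3:
        placed = False
        for _ in range(600):
            w, h = _rect_dims(rng, area)
            hi = int(rng.integers(len(hosts)))
            hx0, hy0, hx1, hy1 = hosts[hi]
            side = int(rng.integers(4))  # 0:right 1:left 2:top 3:bottom
            if side < 2:
                if h >= (hy1 - hy0):
                    continue
                y0 = rng.uniform(hy0, hy1 - h)
                if side == 0:  # sticks out to the right of hx1
                    x0 = hx1 - f * w
                else:  # sticks out to the left of hx0
                    x0 = hx0 - (1.0 - f) * w
                cand = (x0, y0, x0 + w, y0 + h)
            else:
                if w >= (hx1 - hx0):
                    continue
                x0 = rng.uniform(hx0, hx1 - w)
                if side == 2:  # sticks out above hy1
                    y0 = hy1 - f * h
                else:
                    y0 = hy0 - (1.0 - f) * h
                cand = (x0, y0, x0 + w, y0 + h)
            if (
                cand[0] < margin
                or cand[1] < margin
                or cand[2] > box_side - margin
                or cand[3] > box_side - margin
            ):
                continue
            # the protruding part must not meet any other ErbB2 domain
            if any(
                _rects_touch(cand, hosts[k], gap=1e-6) for k in range(len(hosts)) if k != hi
            ):
                continue
            if any(_rects_touch(cand, g, gap=1e-6) for g in guests):
                continue
            guests.append(cand)
            placed = True
            break
        if not placed:
            return None
    return guests
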