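"""Synthetic landscape, pedigree and genotype generator.

Emulates the study system end to end: a grid of multi-storey buildings,
gravitraps placed at three vertical levels in every building, a population of
mosquitoes whose females disperse from their natal site to an oviposition
site by a draw from a configurable dispersal distance kernel (direction
uniform, vertical component confined to the building height range), local
mate choice, Mendelian SNP genotypes descending from founder allele
frequencies, and capture of gravid females by the nearest trap within a short
sampling window.  Ground truth (pedigree, per-individual dispersal distance,
true kin categories) is retained so the close-kin, IBD and density estimators
can be validated against known parameters.

Defaults mirror the study conditions: ~100 captured females per site,
exponential kernel with rate 0.022 per meter (mean ~45 m), tens of thousands
of SNPs, traps across high-rise buildings, captures within an 8-day window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .closekin_kernel import KinPair
from .spatial_io import CaptureRecord, GenotypeTable, TrapRecord, trap_positions_3d

# landscape anchor (Singapore); meters <-> degrees via ellipsoid radii at lat0
_LON0, _LAT0 = 103.85, 1.37
_WGS84_A = 6378137.0
_WGS84_E2 = (1.0 / 298.257223563) * (2.0 - 1.0 / 298.257223563)


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    n_buildings: int = 25                 # laid out on a near-square grid
    building_grid_spacing: float = 70.0   # m between building centers
    n_floors: int = 12
    floor_height: float = 3.0             # m per floor
    kernel_family: str = "exponential"
    kernel_params: dict = field(default_factory=lambda: {"rate": 0.022})
    skip_oviposition_prob: float = 0.2    # chance an egg batch goes to a 2nd site
    mean_offspring: float = 6.0           # Poisson mean per female
    n_generations: int = 3
    n_founders: int = 300                 # also the per-generation carrying capacity
    n_snps: int = 20000
    founder_freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.1
    trap_floors: tuple[int, ...] = (0, 4, 9)
    sampling_window_days: int = 8
    max_captures: int = 100
    mating_range: float | None = None     # defaults to the kernel mean
    seed: int = 0

    def __post_init__(self):
        if min(self.n_buildings, self.n_floors, self.n_founders,
               self.n_generations, self.n_snps) <= 0:
            raise SimulationError("all counts must be positive")
        for p in (self.skip_oviposition_prob, self.missing_rate):
            if not 0 <= p <= 1:
                raise SimulationError("probabilities must be in [0, 1]")


@dataclass
class SimOutput:
    genotypes: GenotypeTable          # captured individuals only
    traps: dict[str, TrapRecord]
    captures: list[CaptureRecord]
    pedigree: pd.DataFrame            # id, generation, sex, mother, father,
    #                                   natal/ovi coordinates, dispersal (m)
    captured_ids: list[str]
    config: SimConfig
    n_same_trap_kin_pairs: int = 0


def _kernel_draw(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    fam, par = cfg.kernel_family, cfg.kernel_params
    if fam == "exponential":
        return rng.exponential(1.0 / par["rate"], size=n)
    if fam == "weibull":
        return par["scale"] * rng.weibull(par["shape"], size=n)
    if fam == "lognormal":
        return rng.lognormal(par["meanlog"], par["sdlog"], size=n)
    raise SimulationError(f"unknown kernel family {fam!r}")


def _kernel_mean(cfg: SimConfig) -> float:
    fam, par = cfg.kernel_family, cfg.kernel_params
    if fam == "exponential":
        return 1.0 / par["rate"]
    if fam == "weibull":
        return par["scale"] * math.gamma(1.0 + 1.0 / par["shape"])
    return math.exp(par["meanlog"] + par["sdlog"] ** 2 / 2.0)


def _disperse(cfg: SimConfig, rng: np.random.Generator,
              origin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Displace each origin by a kernel-length vector with uniform direction.

    The vertical component is confined to [0, building top] by redrawing the
    direction (not the length), so the drawn kernel length is exactly the
    realized 3-D displacement.
    """
    n = origin.shape[0]
    z_max = (cfg.n_floors - 1) * cfg.floor_height
    r = _kernel_draw(cfg, rng, n)
    dest = np.empty_like(origin)
    pending = np.arange(n)
    for _ in range(200):
        m = len(pending)
        if m == 0:
            break
        u = rng.uniform(-1.0, 1.0, size=m)          # cos(polar), uniform on sphere
        theta = rng.uniform(0.0, 2.0 * math.pi, size=m)
        s = np.sqrt(1.0 - u ** 2)
        vec = np.column_stack([s * np.cos(theta), s * np.sin(theta), u]) \
            * r[pending, None]
        cand = origin[pending] + vec
        ok = (cand[:, 2] >= 0.0) & (cand[:, 2] <= z_max)
        dest[pending[ok]] = cand[ok]
        pending = pending[~ok]
    if len(pending):
        # kernel length taller than the whole landscape: flatten to horizontal
        theta = rng.uniform(0.0, 2.0 * math.pi, size=len(pending))
        vec = np.column_stack([np.cos(theta), np.sin(theta),
                               np.zeros(len(pending))]) * r[pending, None]
        dest[pending] = origin[pending] + vec
        dest[pending, 2] = origin[pending, 2]
    return dest, r


def _meters_to_lonlat(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lat0 = math.radians(_LAT0)
    sin2 = math.sin(lat0) ** 2
    r_n = _WGS84_A / math.sqrt(1.0 - _WGS84_E2 * sin2)
    r_m = _WGS84_A * (1.0 - _WGS84_E2) / (1.0 - _WGS84_E2 * sin2) ** 1.5
    lon = _LON0 + np.degrees(np.asarray(x) / (r_n * math.cos(lat0)))
    lat = _LAT0 + np.degrees(np.asarray(y) / r_m)
    return lon, lat


def _build_traps(cfg: SimConfig) -> dict[str, TrapRecord]:
    side = int(math.ceil(math.sqrt(cfg.n_buildings)))
    traps: dict[str, TrapRecord] = {}
    for b in range(cfg.n_buildings):
        bx = (b % side) * cfg.building_grid_spacing
        by = (b // side) * cfg.building_grid_spacing
        lon, lat = _meters_to_lonlat(np.array([bx]), np.array([by]))
        for floor in cfg.trap_floors:
            if floor >= cfg.n_floors:
                continue
            tid = f"T{b:03d}F{floor:02d}"
            traps[tid] = TrapRecord(tid, float(lon[0]), float(lat[0]),
                                    floor * cfg.floor_height, f"B{b:03d}", floor)
    return traps


def _mendelian(rng: np.random.Generator, gm: np.ndarray, gf: np.ndarray) -> np.ndarray:
    """Child dosages by independent segregation from parent dosage rows."""
    a = (rng.random(gm.shape) < gm / 2.0).astype(np.int8)
    b = (rng.random(gf.shape) < gf / 2.0).astype(np.int8)
    return a + b


def simulate_population(cfg: SimConfig) -> SimOutput:
    """Run the landscape/pedigree simulation and emit all pipeline inputs."""
    rng = np.random.default_rng(cfg.seed)
    side = int(math.ceil(math.sqrt(cfg.n_buildings)))
    extent = side * cfg.building_grid_spacing
    z_max = (cfg.n_floors - 1) * cfg.floor_height

    freqs = rng.uniform(*cfg.founder_freq_range, size=cfg.n_snps)

    # founders: Hardy-Weinberg genotypes, natal == oviposition site (no history)
    n0 = cfg.n_founders
    geno = rng.binomial(2, freqs, size=(n0, cfg.n_snps)).astype(np.int8)
    natal = np.column_stack([rng.uniform(0, extent, n0), rng.uniform(0, extent, n0),
                             rng.uniform(0, z_max, n0)])
    sex = rng.random(n0) < 0.5  # True = female
    mother = np.full(n0, -1, dtype=np.int64)
    father = np.full(n0, -1, dtype=np.int64)
    generation = np.zeros(n0, dtype=np.int64)
    ovi = natal.copy()
    dispersal = np.zeros(n0)
    next_id = n0
    cur = np.arange(n0)  # indices of the current generation

    rows = {
        "geno": [geno], "natal": [natal], "ovi": [ovi], "sex": [sex],
        "mother": [mother], "father": [father], "generation": [generation],
        "dispersal": [dispersal],
    }

    def _all(name):
        return np.concatenate(rows[name]) if name != "geno" else np.vstack(rows[name])

    mate_scale = cfg.mating_range or _kernel_mean(cfg)

    for gen in range(1, cfg.n_generations + 1):
        sex_all = _all("sex")
        natal_all = _all("natal")
        females = cur[sex_all[cur]]
        males = cur[~sex_all[cur]]
        if len(females) == 0 or len(males) == 0:
            raise SimulationError(f"population extinct at generation {gen}")

        # females disperse from natal to first oviposition site
        dest, r = _disperse(cfg, rng, natal_all[females])
        ovi_all = _all("ovi")
        ovi_all[females] = dest
        disp_all = _all("dispersal")
        disp_all[females] = r
        _scatter(rows, "ovi", ovi_all)
        _scatter(rows, "dispersal", disp_all)

        # local mate choice: weight ~ exp(-dist / mating range); one mate each
        d2 = ((natal_all[females, None, :2] - natal_all[None, males, :2]) ** 2).sum(-1)
        w = np.exp(-np.sqrt(d2) / mate_scale)
        w_sum = w.sum(axis=1, keepdims=True)
        w = np.where(w_sum > 0, w / w_sum, 1.0 / len(males))
        mates = males[_vectorized_choice(rng, w)]

        # offspring: Poisson families, skip oviposition splits a family across
        # two sites (the second a further kernel step from the first)
        n_off_per = rng.poisson(cfg.mean_offspring, size=len(females))
        total = int(n_off_per.sum())
        if total == 0:
            raise SimulationError(f"population extinct at generation {gen}")
        mom_idx = np.repeat(np.arange(len(females)), n_off_per)
        skip_site, _ = _disperse(cfg, rng, ovi_all[females])
        use_skip = rng.random(total) < cfg.skip_oviposition_prob
        child_natal = np.where(use_skip[:, None], skip_site[mom_idx], ovi_all[females][mom_idx])

        if total > cfg.n_founders:  # carrying capacity keeps the census stable
            keep = np.sort(rng.choice(total, size=cfg.n_founders, replace=False))
        else:
            keep = np.arange(total)
        mom_idx, child_natal = mom_idx[keep], child_natal[keep]
        n_new = len(keep)

        geno_all = _all("geno")
        child_geno = _mendelian(rng, geno_all[females[mom_idx]], geno_all[mates[mom_idx]])
        rows["geno"].append(child_geno)
        rows["natal"].append(child_natal)
        rows["ovi"].append(child_natal.copy())
        rows["sex"].append(rng.random(n_new) < 0.5)
        rows["mother"].append(females[mom_idx].astype(np.int64))
        rows["father"].append(mates[mom_idx].astype(np.int64))
        rows["generation"].append(np.full(n_new, gen, dtype=np.int64))
        rows["dispersal"].append(np.zeros(n_new))
        cur = np.arange(next_id, next_id + n_new)
        next_id += n_new

    # final generation females become gravid, disperse, and may be captured
    sex_all = _all("sex")
    natal_all = _all("natal")
    ovi_all = _all("ovi")
    disp_all = _all("dispersal")
    females = cur[sex_all[cur]]
    if len(females) == 0:
        raise SimulationError("no females to capture in the final generation")
    dest, r = _disperse(cfg, rng, natal_all[females])
    ovi_all[females] = dest
    disp_all[females] = r
    _scatter(rows, "ovi", ovi_all)
    _scatter(rows, "dispersal", disp_all)

    n_cap = min(cfg.max_captures, len(females))
    captured = np.sort(rng.choice(females, size=n_cap, replace=False))

    traps = _build_traps(cfg)
    trap_ids = list(traps)
    # trap positions in landscape meters (building grid + trap height)
    trap_xyz = np.array([[(int(t[1:4]) % side) * cfg.building_grid_spacing,
                          (int(t[1:4]) // side) * cfg.building_grid_spacing,
                          traps[t].height] for t in trap_ids])

    cap_pos = ovi_all[captured]
    d2 = ((cap_pos[:, None, :] - trap_xyz[None, :, :]) ** 2).sum(-1)
    nearest = d2.argmin(axis=1)
    start = date(2018, 5, 1)
    captures = []
    captured_ids = [f"ind{int(i)}" for i in captured]
    offsets = rng.integers(0, cfg.sampling_window_days, size=n_cap)
    for iid, t_idx, off in zip(captured_ids, nearest, offsets):
        captures.append(CaptureRecord(iid, trap_ids[int(t_idx)],
                                      start + timedelta(days=int(off))))

    geno_all = _all("geno")
    calls = geno_all[captured].copy()
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = -1
    gt = GenotypeTable(captured_ids, [f"snp{k}" for k in range(cfg.n_snps)], calls)

    ped = pd.DataFrame({
        "id": [f"ind{i}" for i in range(next_id)],
        "generation": _all("generation"),
        "sex": np.where(_all("sex"), "F", "M"),
        "mother": [f"ind{m}" if m >= 0 else "" for m in _all("mother")],
        "father": [f"ind{f}" if f >= 0 else "" for f in _all("father")],
        "natal_x": _all("natal")[:, 0], "natal_y": _all("natal")[:, 1],
        "natal_z": _all("natal")[:, 2],
        "ovi_x": _all("ovi")[:, 0], "ovi_y": _all("ovi")[:, 1],
        "ovi_z": _all("ovi")[:, 2],
        "dispersal": _all("dispersal"),
    })
    return SimOutput(genotypes=gt, traps=traps, captures=captures, pedigree=ped,
                     captured_ids=captured_ids, config=cfg)


def _scatter(rows: dict, name: str, full: np.ndarray) -> None:
    """Write a concatenated array back into the per-generation chunks."""
    off = 0
    for k, chunk in enumerate(rows[name]):
        rows[name][k] = full[off:off + len(chunk)]
        off += len(chunk)


def _vectorized_choice(rng: np.random.Generator, w: np.ndarray) -> np.ndarray:
    """One categorical draw per row of a row-stochastic weight matrix."""
    cum = np.cumsum(w, axis=1)
    u = rng.random(w.shape[0])[:, None] * cum[:, -1:]
    return (u > cum).sum(axis=1)


# ---------------------------------------------------------------------------
# pedigree truth


def _true_categories(ped: pd.DataFrame, ids: list[str]) -> dict[tuple[str, str], str]:
    """True kin category per captured pair, derived from the pedigree.

    PO/FS outrank SECOND (half-sib, avuncular, grandparent-grandoffspring),
    which outranks THIRD (first cousins).
    """
    parents = dict(zip(ped["id"], zip(ped["mother"], ped["father"])))
    rank = {"PO": 0, "FS": 0, "SECOND": 1, "THIRD": 2}
    out: dict[tuple[str, str], str] = {}

    def put(a, b, cat):
        key = (a, b) if a < b else (b, a)
        if key not in out or rank[cat] < rank[out[key]]:
            out[key] = cat

    idset = set(ids)
    # PO and grandparent-grandoffspring
    for a in ids:
        m, f = parents.get(a, ("", ""))
        for p in (m, f):
            if p in idset:
                put(a, p, "PO")
            if p and p in parents:
                for gp in parents[p]:
                    if gp in idset:
                        put(a, gp, "SECOND")
    # FS and HS via parent grouping
    by_pair: dict[tuple[str, str], list[str]] = {}
    by_parent: dict[str, list[str]] = {}
    for a in ids:
        m, f = parents.get(a, ("", ""))
        if m and f:
            by_pair.setdefault((m, f), []).append(a)
        for p in (m, f):
            if p:
                by_parent.setdefault(p, []).append(a)
    for group in by_pair.values():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                put(group[i], group[j], "FS")
    for group in by_parent.values():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                if parents.get(a) != parents.get(b):
                    put(a, b, "SECOND")  # half siblings
    # avuncular: b is a full sibling of a parent of a
    self_key = {a: parents.get(a, ("", "")) for a in ids}
    for a in ids:
        for p in parents.get(a, ("", "")):
            if p and p in parents and all(parents[p]):
                for b in ids:
                    if b != a and b != p and self_key[b] == parents[p]:
                        put(a, b, "SECOND")
    # first cousins: a parent of each are full siblings
    by_gp: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for a in ids:
        for p in parents.get(a, ("", "")):
            if p and p in parents and all(parents[p]):
                by_gp.setdefault(parents[p], []).append((a, p))
    for group in by_gp.values():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                (a, pa), (b, pb) = group[i], group[j]
                if a != b and pa != pb:
                    put(a, b, "THIRD")
    return out


def truth_kin_pairs(out: SimOutput) -> tuple[list[KinPair], int]:
    """Pedigree-true close-kin pairs among captured individuals.

    Pair separation is the 3-D distance between the capture traps (what the
    field analysis observes).  Same-trap pairs (zero distance) are excluded,
    and their count returned alongside.
    """
    cats = _true_categories(out.pedigree, out.captured_ids)
    pos = trap_positions_3d(out.traps)
    trap_of = {c.individual_id: c.trap_id for c in out.captures}
    pairs, n_same = [], 0
    for (a, b), cat in sorted(cats.items()):
        xa, xb = pos[trap_of[a]], pos[trap_of[b]]
        d = float(np.linalg.norm(xa - xb))
        if d <= 0:
            n_same += 1
            continue
        pairs.append(KinPair(a, b, cat, d))
    return pairs, n_same


# ---------------------------------------------------------------------------
# writers (the same plain-text formats spatial_io reads)


def write_traps_csv(out: SimOutput, path) -> None:
    pd.DataFrame([
        {"trap_id": t.trap_id, "lon": t.lon, "lat": t.lat, "height": t.height,
         "building": t.building_id, "floor": t.floor}
        for t in out.traps.values()
    ]).to_csv(path, index=False)


def write_captures_csv(out: SimOutput, path) -> None:
    pd.DataFrame([
        {"individual_id": c.individual_id, "trap_id": c.trap_id,
         "date": c.date.isoformat()}
        for c in out.captures
    ]).to_csv(path, index=False)


def write_vcf(out: SimOutput, path) -> None:
    g = out.genotypes
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=1>\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.individual_ids) + "\n")
        for k, sid in enumerate(g.site_ids):
            calls = "\t".join(gt_str[int(v)] for v in g.calls[:, k])
            fh.write(f"1\t{k + 1}\t{sid}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def write_truth(out: SimOutput, pedigree_path, kin_path, dispersal_path) -> None:
    out.pedigree.to_csv(pedigree_path, index=False)
    pairs, n_same = truth_kin_pairs(out)
    pd.DataFrame([
        {"id1": p.id1, "id2": p.id2, "category": p.category, "distance_m": p.d}
        for p in pairs
    ]).to_csv(kin_path, index=False)
    cap = out.pedigree[out.pedigree["id"].isin(out.captured_ids)]
    cap[["id", "dispersal"]].to_csv(dispersal_path, index=False)
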