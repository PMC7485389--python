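"""Synthetic discharge cohorts with planted comorbidity structure.

The generator emulates the statistical shape of a specialized-hospital
discharge registry: ~10^3-10^4 records, each carrying a handful of ICD-10
codes, with planted comorbidity modules, one hub disease per module,
age-dependent module prevalence, and module-aligned gene pools. The
mechanism is latent-module-per-record: every record draws a hidden module,
then samples its codes with the module's diseases up-weighted by a
configurable odds boost (boost = 1 recovers fully independent diseases,
the null model). Patients thereby "accumulate diseases from a
physiopathological cluster", which is exactly the signal the network
pipeline is built to detect.

Everything is deterministic given ``SimConfig.seed``; emitted files are
byte-identical across runs with the same config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ora import PathwayCollection
from .records_io import DischargeRecord, RecordSet, default_age_brackets

_MODULE_LETTERS = "QINEGJKDRC"  # ICD-10 chapter-like letters, one per module


@dataclass
class SimConfig:
    """Study conditions for the simulated cohort.

    Defaults describe a 5,000-record cohort with 60 diseases in three
    planted modules of 20 (congenital-, ischemic- and renal-flavoured code
    letters), a strong within-module co-occurrence boost, one oversampled
    hub per module, and ClinVar-like annotation coverage of 40%.
    """

    n_records: int = 5000
    n_diseases: int = 60
    n_modules: int = 3
    within_module_cooccurrence_boost: float = 40.0
    background_pair_rate: float = 1.0  # baseline sampling weight of any disease
    min_codes_per_record: int = 2
    max_codes_per_record: int = 6
    hub_per_module: bool = True
    hub_weight: float = 4.0  # extra within-pool weight of the hub disease
    age_profile: dict[int, list[float]] | None = None  # module -> 10 bracket weights
    annotation_probability: float = 0.4
    genes_per_module_pool: int = 40
    background_gene_pool: int = 100
    gene_inclusion_rate: float = 0.75  # per-gene chance an annotated disease samples its pool gene
    noise_genes_mean: float = 3.0
    pathway_alignment: bool = True
    n_decoy_pathways: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_modules <= self.n_diseases):
            raise ValueError("need 1 <= n_modules <= n_diseases")
        if self.max_codes_per_record > self.n_diseases:
            raise ValueError("max_codes_per_record exceeds n_diseases")
        if not (1 <= self.min_codes_per_record <= self.max_codes_per_record):
            raise ValueError("need 1 <= min_codes <= max_codes")
        if self.within_module_cooccurrence_boost < 1:
            raise ValueError("boost must be >= 1")
        for p in (self.annotation_probability, self.gene_inclusion_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure the pipeline is expected to recover."""

    module_of: dict[str, int]  # disease code -> planted module id
    hubs: list[str]
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    aligned_pathways: dict[int, str] = field(default_factory=dict)

    def within_module_pairs(self) -> list[tuple[str, str]]:
        """All unordered same-module disease pairs (the planted strong pairs)."""
        pairs = []
        codes = sorted(self.module_of)
        for i, a in enumerate(codes):
            for b in codes[i + 1:]:
                if self.module_of[a] == self.module_of[b]:
                    pairs.append((a, b))
        return pairs

    def to_json(self) -> str:
        return json.dumps(
            {
                "module_of": self.module_of,
                "hubs": self.hubs,
                "gene_sets": {c: sorted(g) for c, g in self.gene_sets.items()},
                "aligned_pathways": {str(m): p for m, p in self.aligned_pathways.items()},
            },
            indent=1,
            sort_keys=True,
        )


def _disease_codes(cfg: SimConfig) -> tuple[list[str], dict[str, int]]:
    """Valid ICD-10-looking codes, one letter block per planted module."""
    sizes = [cfg.n_diseases // cfg.n_modules] * cfg.n_modules
    for i in range(cfg.n_diseases % cfg.n_modules):
        sizes[i] += 1
    codes, module_of = [], {}
    for m, size in enumerate(sizes):
        letter = _MODULE_LETTERS[m % len(_MODULE_LETTERS)]
        for i in range(size):
            code = f"{letter}{(m // len(_MODULE_LETTERS)) * 50 + i:02d}.X"
            codes.append(code)
            module_of[code] = m
    return codes, module_of


def _default_age_profile(n_modules: int) -> dict[int, list[float]]:
    """Peaked bracket weights: module 0 young (congenital-like), later
    modules progressively older (ischemic/systemic-like)."""
    profiles = {}
    for m in range(n_modules):
        peak = 9 * m / (n_modules - 1) if n_modules > 1 else 4.5
        w = [float(np.exp(-0.5 * ((j - peak) / 1.5) ** 2)) for j in range(10)]
        total = sum(w)
        profiles[m] = [x / total for x in w]
    return profiles


def generate_cohort(cfg: SimConfig) -> tuple[RecordSet, GroundTruth]:
    """Sample the discharge cohort and its ground truth.

    Per record: a latent module (uniform), an age from that module's
    bracket-weight profile, a sex, and 2-6 distinct codes drawn without
    replacement with weights boosted for the latent module's diseases
    (hub further oversampled).
    """
    rng = np.random.default_rng(cfg.seed)
    codes, module_of = _disease_codes(cfg)
    hubs = []
    if cfg.hub_per_module:
        seen = set()
        for c in codes:
            if module_of[c] not in seen:
                hubs.append(c)
                seen.add(module_of[c])
    profile = cfg.age_profile or _default_age_profile(cfg.n_modules)
    brackets = default_age_brackets()
    code_arr = np.array(codes)
    base = np.full(len(codes), cfg.background_pair_rate)
    module_masks = {m: np.array([module_of[c] == m for c in codes]) for m in range(cfg.n_modules)}
    hub_idx = {module_of[h]: codes.index(h) for h in hubs}

    records = []
    for i in range(cfg.n_records):
        m = int(rng.integers(cfg.n_modules))
        j = int(rng.choice(10, p=profile[m]))
        b = brackets[j]
        hi = b.hi if b.hi is not None else 100
        age = int(rng.integers(b.lo, hi + 1))
        sex = "female" if rng.random() < 0.5 else "male"
        n_codes = int(rng.integers(cfg.min_codes_per_record, cfg.max_codes_per_record + 1))
        w = base.copy()
        w[module_masks[m]] *= cfg.within_module_cooccurrence_boost
        if m in hub_idx:
            w[hub_idx[m]] *= cfg.hub_weight
        picked = rng.choice(code_arr, size=n_codes, replace=False, p=w / w.sum())
        records.append(DischargeRecord(f"r{i:05d}", age, sex, frozenset(picked.tolist())))
    rs = RecordSet(records, provenance=f"synthetic(seed={cfg.seed})")
    return rs, GroundTruth(module_of, hubs)


def generate_annotations(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[dict[str, frozenset[str]], PathwayCollection, GroundTruth]:
    """Attach module-aligned gene pools and pathways to the planted diseases.

    Each module owns a gene pool; an annotated disease samples most of its
    module's pool plus a few background-pool noise genes, so within-module
    pairs share many genes (high Jaccard) and between-module pairs share
    almost none. When ``pathway_alignment`` is on, one pathway per module
    equals the module's pool; decoy pathways are background-pool samples.
    """
    rng = np.random.default_rng((cfg.seed + 1) % 2**31)
    pools = {
        m: [f"M{m}G{i:03d}" for i in range(cfg.genes_per_module_pool)]
        for m in range(cfg.n_modules)
    }
    background = [f"BG{i:03d}" for i in range(cfg.background_gene_pool)]

    ann: dict[str, frozenset[str]] = {}
    gene_sets: dict[str, list[str]] = {}
    for code in sorted(truth.module_of):
        if rng.random() >= cfg.annotation_probability:
            continue
        pool = pools[truth.module_of[code]]
        keep = [g for g in pool if rng.random() < cfg.gene_inclusion_rate]
        n_noise = min(int(rng.poisson(cfg.noise_genes_mean)), len(background))
        noise = rng.choice(background, size=n_noise, replace=False).tolist() if n_noise else []
        genes = frozenset(keep + noise)
        if genes:
            ann[code] = genes
            gene_sets[code] = sorted(genes)

    pathways: dict[str, frozenset[str]] = {}
    aligned: dict[int, str] = {}
    if cfg.pathway_alignment:
        for m, pool in pools.items():
            name = f"PATH_M{m}"
            pathways[name] = frozenset(pool)
            aligned[m] = name
    for d in range(cfg.n_decoy_pathways):
        size = min(cfg.genes_per_module_pool, len(background))
        pathways[f"PATH_DECOY{d}"] = frozenset(
            rng.choice(background, size=size, replace=False).tolist()
        )
    universe = frozenset(g for pool in pools.values() for g in pool) | frozenset(background)
    coll = PathwayCollection(pathways, universe)
    truth.gene_sets = gene_sets
    truth.aligned_pathways = aligned
    return ann, coll, truth


# --- file emission ------------------------------------------------------

def records_frame(rs: RecordSet) -> pd.DataFrame:
    """Long-format frame (record_id, age, sex, icd10), one diagnosis per row."""
    rows = [
        (r.record_id, r.age, {"female": "F", "male": "M"}.get(r.sex, "U"), code)
        for r in rs
        for code in sorted(r.codes)
    ]
    return pd.DataFrame(rows, columns=["record_id", "age", "sex", "icd10"])


def write_dataset(cfg: SimConfig, outdir) -> dict[str, str]:
    """Emit records.tsv, annotations.tsv, pathways.gmt and truth.json.

    Deterministic and byte-identical for identical configs.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rs, truth = generate_cohort(cfg)
    ann, coll, truth = generate_annotations(cfg, truth)

    paths = {name: str(out / fname) for name, fname in [
        ("records", "records.tsv"), ("annotations", "annotations.tsv"),
        ("pathways", "pathways.gmt"), ("truth", "truth.json"),
    ]}
    records_frame(rs).to_csv(paths["records"], sep="\t", index=False)
    pd.DataFrame(
        [(c, g) for c in sorted(ann) for g in sorted(ann[c])], columns=["icd10", "gene"]
    ).to_csv(paths["annotations"], sep="\t", index=False)
    with open(paths["pathways"], "w") as fh:
        for name in sorted(coll.pathways):
            genes = "\t".join(sorted(coll.pathways[name]))
            fh.write(f"{name}\tsynthetic\t{genes}\n")
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
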