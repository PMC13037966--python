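"""Synthetic TPM studies with known differential co-expression ground truth.

The generator emulates the canonical study layout — three cell lines (two with
the responsive Phenotype A, one reference Phenotype B), two treatments
(control ``DMSO`` and compound ``GL24``), five replicates per group — and
plants structures whose intended downstream behaviour is known:

* **DS1 pairs** — correlated in the treated groups of both A lines, enforced
  uncorrelated everywhere else (gain of co-expression).
* **DS2 pairs** — the mirror image: correlated in the A-line control groups.
* **DS3 pairs** — correlated in all four A-line groups, with a different
  correlation strength under treatment.
* **non-differential pairs** — identically behaved in every group: half are
  correlated everywhere at the same strength, half uncorrelated everywhere.
* **NA genes** — background genes emitting exact zeros across all replicates
  of designated groups.
* **a planted cluster and a hub star** — DS1-style structures (a certified
  chain of correlated members, and a star of certified spokes) for component-
  and hub-recovery tests.

Correlated plants are constructed with an *exact sample* correlation equal to
``r_target`` (noise confined to the orthogonal complement of the latent
vector), the realized draw is additionally required to be rank-comonotone
with the latent and to survive the exact 120-ordering permutation test with
zero beats. This matters: at n = 5 a *population* correlation of 0.99 drops
below the P < 0.005 boundary about a quarter of the time, and even an exact
sample r = 0.99 is beaten by some alternative pairing of the points roughly
half the time unless the ranks align. Without these guarantees the emitted
ground-truth labels would simply be false in the data; with them, recovery
tests measure the pipeline rather than generator sampling noise. Groups where
a plant is intended uncorrelated are redrawn until the parametric p exceeds
0.1, a margin above the NS threshold of 0.05.

Background genes are independent log-normal TPM: a per-gene baseline
(log-mean ``tpm_location``, log-sd ``tpm_scale``, the across-gene spread) times
modest per-replicate log-normal noise (log-sd ``replicate_scale``), roughly a
40 % replicate CV. Real RNA-seq features deliberately not emulated: library
-size/compositional artifacts, batch effects, count noise, gene length bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import empirical_p, pearson_p_from_r, pearson_with_p
from .expression_data import (
    ExpressionMatrix,
    GroupKey,
    StudyDesign,
    TreatmentPair,
)

CONTROL = "DMSO"
TREATED = "GL24"
A_LINES = ("A1", "A2")
B_LINES = ("B1",)

_MAX_REDRAWS = 1000
_NS_MARGIN_P = 0.1  # intended-uncorrelated groups are redrawn until p > this


class SyntheticSpecError(ValueError):
    """Raised for internally inconsistent generator specifications."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-generator parameters.

    Defaults mirror the canonical benchmark: 200 pure-background genes,
    50 DS1 + 50 DS2 planted pairs at r_target = 0.99, 20 non-differential
    pairs, 10 NA genes, one 27-gene cluster, one degree-10 hub star, and
    5 replicates per group.
    """

    n_background_genes: int = 200
    n_ds1_pairs: int = 50
    n_ds2_pairs: int = 50
    n_ds3_pairs: int = 0
    n_nondiff_pairs: int = 20
    n_na_genes: int = 10
    planted_cluster_sizes: tuple[int, ...] = (27,)
    hub_degree: int = 10
    r_target: float = 0.99
    ds3_r_treated: float = 0.90
    replicates_per_group: int = 5
    tpm_location: float = 3.0
    tpm_scale: float = 1.5
    replicate_scale: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_background_genes,
            self.n_ds1_pairs,
            self.n_ds2_pairs,
            self.n_ds3_pairs,
            self.n_nondiff_pairs,
            self.n_na_genes,
            self.hub_degree,
        )
        if any(c < 0 for c in counts):
            raise SyntheticSpecError("all counts must be >= 0")
        if not 0 < self.r_target <= 1:
            raise SyntheticSpecError("r_target must be in (0, 1]")
        if self.r_target < 0.98:
            # documented floor: at n=5 the P < 0.005 boundary sits at |r|=0.9737
            raise SyntheticSpecError(
                "r_target must be >= 0.98 so planted pairs clear P < 0.005 at n=5"
            )
        if self.replicates_per_group < 3:
            raise SyntheticSpecError("replicates_per_group must be >= 3")
        if any(k < 2 for k in self.planted_cluster_sizes):
            raise SyntheticSpecError("planted cluster sizes must be >= 2")
        if self.n_na_genes > self.n_background_genes:
            raise SyntheticSpecError(
                "n_na_genes exceeds n_background_genes: NA genes are background "
                "genes zeroed in designated groups"
            )


#: truth-manifest columns (one long table covering all planted entities)
TRUTH_COLUMNS = [
    "kind",  # pair / cluster_member / hub_center / hub_leaf / na_gene
    "structure_id",
    "gene_a",
    "gene_b",
    "scenario",  # DS1 / DS2 / DS3 / nondiff / "" for NA genes
    "guaranteed",  # per-group labels certified by construction
    "sign",  # + / - / ""
    "cell_line",  # for na_gene rows: affected group
    "treatment",
]


@dataclass
class GroundTruth:
    """What was planted where; the scoring harness consumes this."""

    pairs: pd.DataFrame  # pair-level rows (incl. within-cluster, hub spokes)
    clusters: dict[str, list[str]]  # structure_id -> member genes
    hub_center: str | None
    hub_leaves: list[str]
    na_genes: pd.DataFrame  # gene, cell_line, treatment of affected groups

    def scenario_pairs(self, scenario: str, guaranteed_only: bool = False) -> set[tuple[str, str]]:
        df = self.pairs[self.pairs["scenario"] == scenario]
        if guaranteed_only:
            df = df[df["guaranteed"]]
        return {tuple(sorted((a, b))) for a, b in zip(df["gene_a"], df["gene_b"])}


def _noise_vector(rng: np.random.Generator, n: int, spec: SyntheticSpec) -> np.ndarray:
    base = rng.lognormal(spec.tpm_location, spec.tpm_scale)
    return base * rng.lognormal(0.0, spec.replicate_scale, n)


def _exact_corr_partner(
    rng: np.random.Generator,
    x: np.ndarray,
    r: float,
    sign: int,
    spec: SyntheticSpec,
    certify: bool,
) -> np.ndarray:
    """A vector whose sample correlation with ``x`` is exactly ``sign * r``.

    The noise component lives in the orthogonal complement of the centered,
    standardized ``x``. The draw is redrawn until the partner is rank-aligned
    with ``sign * x`` and (when ``certify``) until the exact permutation
    enumeration yields zero beats, so a planted "significant" really is one.
    """
    n = x.size
    xs = x - x.mean()
    xn = np.linalg.norm(xs)
    if xn == 0:
        raise ValueError("latent vector must not be constant")
    xs = xs / xn
    target_ranks = np.argsort(np.argsort(sign * x))
    s = math.sqrt(max(0.0, 1.0 - r * r))
    for _ in range(_MAX_REDRAWS):
        z = rng.normal(size=n)
        z = z - z.mean()
        z = z - (z @ xs) * xs
        zn = np.linalg.norm(z)
        if zn < 1e-12:
            continue
        w = sign * r * xs + s * (z / zn)
        if not np.array_equal(np.argsort(np.argsort(w)), target_ranks):
            continue
        # shift/scale onto a TPM-like range; affine maps preserve r exactly
        scale = float(np.std(x)) or 1.0
        y = scale * (w - w.min()) / (np.ptp(w) or 1.0) * 2.0 + 0.25 * scale
        if certify:
            r_obs, p_obs = pearson_with_p(x, y)
            if not (p_obs < 0.005) or empirical_p(x, y, p_obs, exact=True) != 0.0:
                continue
        return y
    raise RuntimeError("failed to construct a certified correlated partner")


def _uncorrelated_partner(
    rng: np.random.Generator, x: np.ndarray, spec: SyntheticSpec
) -> np.ndarray:
    """Independent noise redrawn until clearly non-significant against ``x``."""
    for _ in range(_MAX_REDRAWS):
        y = _noise_vector(rng, x.size, spec)
        _, p = pearson_with_p(x, y)
        if p > _NS_MARGIN_P:
            return y
    raise RuntimeError("failed to draw an uncorrelated partner")


def _uncorrelated_pair(
    rng: np.random.Generator, n: int, spec: SyntheticSpec
) -> tuple[np.ndarray, np.ndarray]:
    x = _noise_vector(rng, n, spec)
    return x, _uncorrelated_partner(rng, x, spec)


def plant_cluster(
    rng: np.random.Generator,
    size: int,
    spec: SyntheticSpec,
    group_keys: list[GroupKey],
    correlated_groups: list[GroupKey],
) -> list[dict[GroupKey, np.ndarray]]:
    """Per-group vectors for ``size`` genes forming one guaranteed component.

    Members are built as a chain: each member is a *certified* exact-r_target
    partner of the previous member within the designated groups and an
    enforced-uncorrelated partner of it everywhere else. Every chain edge is
    therefore a guaranteed significant pair in the designated groups and a
    guaranteed non-significant one elsewhere, so the chain alone connects all
    ``size`` genes; non-adjacent members correlate at roughly
    ``r_target**distance`` and may contribute extra edges opportunistically.
    """
    if size < 2:
        raise ValueError("cluster size must be >= 2")
    n = spec.replicates_per_group
    members: list[dict[GroupKey, np.ndarray]] = [
        {key: _noise_vector(rng, n, spec) for key in group_keys}
    ]
    for _ in range(size - 1):
        prev = members[-1]
        per: dict[GroupKey, np.ndarray] = {}
        for key in group_keys:
            if key in correlated_groups:
                per[key] = _exact_corr_partner(
                    rng, prev[key], spec.r_target, 1, spec, certify=True
                )
            else:
                per[key] = _uncorrelated_partner(rng, prev[key], spec)
        members.append(per)
    return members


def _study_design(spec: SyntheticSpec) -> StudyDesign:
    groups: dict[GroupKey, list[str]] = {}
    pairs: list[TreatmentPair] = []
    roles: dict[str, str] = {}
    for line in A_LINES + B_LINES:
        roles[line] = "A" if line in A_LINES else "B"
        for trt in (CONTROL, TREATED):
            groups[(line, trt)] = [
                f"{line}_{trt}_{i + 1}" for i in range(spec.replicates_per_group)
            ]
        pairs.append(TreatmentPair(line, CONTROL, TREATED))
    return StudyDesign(
        groups, pairs, roles, min_replicates=min(5, spec.replicates_per_group)
    )


def generate_study(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, StudyDesign, GroundTruth]:
    """Generate a full synthetic study; bitwise reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    design = _study_design(spec)
    n = spec.replicates_per_group
    group_keys = list(design.groups)  # insertion order: A1, A2, B1 x (DMSO, GL24)
    a_treated = [(line, TREATED) for line in A_LINES]
    a_control = [(line, CONTROL) for line in A_LINES]

    gene_rows: dict[str, dict[GroupKey, np.ndarray]] = {}
    truth_rows: list[dict] = []
    na_rows: list[dict] = []

    def add_gene(gene: str, per_group: dict[GroupKey, np.ndarray]) -> None:
        gene_rows[gene] = per_group

    def fill_noise(exclude: dict[GroupKey, np.ndarray] | None = None) -> dict:
        out = dict(exclude or {})
        for key in group_keys:
            if key not in out:
                out[key] = _noise_vector(rng, n, spec)
        return out

    # --- background genes (the first n_na_genes become NA genes) ------------
    background: list[str] = []
    for i in range(spec.n_background_genes):
        gene = f"BG_{i + 1:04d}"
        background.append(gene)
        add_gene(gene, fill_noise())
    for i in range(spec.n_na_genes):
        gene = background[i]
        # alternate: zero everywhere / zero in all control groups only
        affected = (
            group_keys
            if i % 2 == 0
            else [k for k in group_keys if k[1] == CONTROL]
        )
        for key in affected:
            gene_rows[gene][key] = np.zeros(n)
            na_rows.append({"gene": gene, "cell_line": key[0], "treatment": key[1]})

    def plant_pair(
        prefix: str,
        idx: int,
        scenario: str,
        correlated_groups: list[GroupKey],
        r: float | dict[GroupKey, float],
        sign: int,
        certify: bool = True,
    ) -> tuple[str, str]:
        ga, gb = f"{prefix}{idx + 1:03d}a", f"{prefix}{idx + 1:03d}b"
        per_a: dict[GroupKey, np.ndarray] = {}
        per_b: dict[GroupKey, np.ndarray] = {}
        for key in group_keys:
            x = _noise_vector(rng, n, spec)
            per_a[key] = x
            if key in correlated_groups:
                rk = r[key] if isinstance(r, dict) else r
                per_b[key] = _exact_corr_partner(rng, x, rk, sign, spec, certify=certify)
            else:
                per_b[key] = _uncorrelated_partner(rng, x, spec)
        add_gene(ga, per_a)
        add_gene(gb, per_b)
        truth_rows.append(
            {
                "kind": "pair",
                "structure_id": f"{prefix}{idx + 1:03d}",
                "gene_a": ga,
                "gene_b": gb,
                "scenario": scenario,
                "guaranteed": certify,
                "sign": "+" if sign > 0 else "-",
                "cell_line": "",
                "treatment": "",
            }
        )
        return ga, gb

    # --- DS1 / DS2 / DS3 / non-differential pairs ---------------------------
    for i in range(spec.n_ds1_pairs):
        plant_pair("D1P", i, "DS1", a_treated, spec.r_target, 1 if i % 2 == 0 else -1)
    for i in range(spec.n_ds2_pairs):
        plant_pair("D2P", i, "DS2", a_control, spec.r_target, 1 if i % 2 == 0 else -1)
    for i in range(spec.n_ds3_pairs):
        r_by_group = {key: spec.r_target for key in a_control}
        r_by_group.update({key: spec.ds3_r_treated for key in a_treated})
        plant_pair(
            "D3P",
            i,
            "DS3",
            a_control + a_treated,
            r_by_group,
            1,
            certify=False,  # the weaker treated correlation cannot be certified
        )
    for i in range(spec.n_nondiff_pairs):
        if i % 2 == 0:  # correlated everywhere, same strength
            plant_pair("NDP", i, "nondiff", list(group_keys), spec.r_target, 1)
        else:  # uncorrelated everywhere
            ga, gb = f"NDP{i + 1:03d}a", f"NDP{i + 1:03d}b"
            per_a, per_b = {}, {}
            for key in group_keys:
                x, y = _uncorrelated_pair(rng, n, spec)
                per_a[key], per_b[key] = x, y
            add_gene(ga, per_a)
            add_gene(gb, per_b)
            truth_rows.append(
                {
                    "kind": "pair",
                    "structure_id": f"NDP{i + 1:03d}",
                    "gene_a": ga,
                    "gene_b": gb,
                    "scenario": "nondiff",
                    "guaranteed": True,
                    "sign": "",
                    "cell_line": "",
                    "treatment": "",
                }
            )

    # --- planted clusters (DS1-style: correlated in A-treated groups) -------
    clusters: dict[str, list[str]] = {}
    for ci, size in enumerate(spec.planted_cluster_sizes):
        cid = f"CL{ci + 1}"
        members = [f"{cid}_{j + 1:03d}" for j in range(size)]
        clusters[cid] = members
        blocks = plant_cluster(rng, size, spec, group_keys, a_treated)
        for gene, per in zip(members, blocks):
            add_gene(gene, per)
        for j in range(size):
            for l in range(j + 1, size):
                truth_rows.append(
                    {
                        "kind": "cluster_member",
                        "structure_id": cid,
                        "gene_a": members[j],
                        "gene_b": members[l],
                        "scenario": "DS1",
                        "guaranteed": l == j + 1,  # chain edges are certified
                        "sign": "+",
                        "cell_line": "",
                        "treatment": "",
                    }
                )

    # --- hub star (DS1-style; spokes certified, so degree is guaranteed) ----
    hub_center: str | None = None
    hub_leaves: list[str] = []
    if spec.hub_degree > 0:
        hub_center = "HUB_C"
        center_per = fill_noise()
        add_gene(hub_center, center_per)
        for j in range(spec.hub_degree):
            leaf = f"HUB_L{j + 1:02d}"
            hub_leaves.append(leaf)
            per: dict[GroupKey, np.ndarray] = {}
            for key in group_keys:
                if key in a_treated:
                    per[key] = _exact_corr_partner(
                        rng, center_per[key], spec.r_target, 1, spec, certify=True
                    )
                else:
                    per[key] = _uncorrelated_partner(rng, center_per[key], spec)
            add_gene(leaf, per)
            truth_rows.append(
                {
                    "kind": "hub_spoke",
                    "structure_id": "HUB",
                    "gene_a": hub_center,
                    "gene_b": leaf,
                    "scenario": "DS1",
                    "guaranteed": True,
                    "sign": "+",
                    "cell_line": "",
                    "treatment": "",
                }
            )
        for j in range(spec.hub_degree):
            for l in range(j + 1, spec.hub_degree):
                truth_rows.append(
                    {
                        "kind": "hub_leaf_pair",
                        "structure_id": "HUB",
                        "gene_a": hub_leaves[j],
                        "gene_b": hub_leaves[l],
                        "scenario": "DS1",
                        "guaranteed": False,
                        "sign": "+",
                        "cell_line": "",
                        "treatment": "",
                    }
                )

    # --- assemble the matrix ------------------------------------------------
    genes = list(gene_rows)
    samples = [s for key in group_keys for s in design.groups[key]]
    data = np.empty((len(genes), len(samples)))
    col = 0
    for key in group_keys:
        width = len(design.groups[key])
        for gi, gene in enumerate(genes):
            data[gi, col : col + width] = gene_rows[gene][key]
        col += width
    matrix = ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples))

    truth = GroundTruth(
        pairs=pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS),
        clusters=clusters,
        hub_center=hub_center,
        hub_leaves=hub_leaves,
        na_genes=pd.DataFrame(na_rows, columns=["gene", "cell_line", "treatment"]),
    )
    return matrix, design, truth


def write_truth_manifest(truth: GroundTruth, path: str | Path) -> None:
    """Serialize the ground truth as one TSV manifest (round-trippable)."""
    rows = truth.pairs.copy()
    na = truth.na_genes.copy()
    if not na.empty:
        na_block = pd.DataFrame(
            {
                "kind": "na_gene",
                "structure_id": "NA",
                "gene_a": na["gene"],
                "gene_b": "",
                "scenario": "",
                "guaranteed": True,
                "sign": "",
                "cell_line": na["cell_line"],
                "treatment": na["treatment"],
            }
        )
        rows = pd.concat([rows, na_block], ignore_index=True)
    rows.to_csv(path, sep="\t", index=False)


def read_truth_manifest(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in TRUTH_COLUMNS if c != "guaranteed"},
                     keep_default_na=False)
    if list(df.columns) != TRUTH_COLUMNS:
        raise ValueError(f"unexpected manifest columns in {path}")
    df["guaranteed"] = df["guaranteed"].astype(str).str.lower().isin(("true", "1"))
    na = df[df["kind"] == "na_gene"]
    pairs = df[df["kind"] != "na_gene"].reset_index(drop=True)
    clusters: dict[str, list[str]] = {}
    cm = pairs[pairs["kind"] == "cluster_member"]
    for cid, sub in cm.groupby("structure_id"):
        clusters[str(cid)] = sorted(set(sub["gene_a"]) | set(sub["gene_b"]))
    spokes = pairs[pairs["kind"] == "hub_spoke"]
    hub_center = str(spokes["gene_a"].iloc[0]) if not spokes.empty else None
    hub_leaves = sorted(spokes["gene_b"]) if not spokes.empty else []
    return GroundTruth(
        pairs=pairs,
        clusters=clusters,
        hub_center=hub_center,
        hub_leaves=hub_leaves,
        na_genes=pd.DataFrame(
            {
                "gene": na["gene_a"].to_numpy(),
                "cell_line": na["cell_line"].to_numpy(),
                "treatment": na["treatment"].to_numpy(),
            }
        ),
    )
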