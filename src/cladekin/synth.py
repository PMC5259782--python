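"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume —
clade-structured protein alignments with planted reference-unique and
clade-discriminating columns (plus optional indel columns so alignment
coordinates and residue positions diverge), Michaelis-Menten assay data
with multiplicative replicate noise and multiplicative effector action,
and unimodal (Gaussian) pH/temperature activity profiles.  Each output
is paired with a truth record, which is the oracle the tests and the
acceptance checks compare against.

Everything is a pure function of (config, seed): the same inputs
regenerate byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .kinetics import EPSILON_NADH_340, MOCK, ActivityProfile, AssayTrace, Condition
from .seq_core import AMINO_ACIDS, GAP_CHAR, Alignment, ProteinSequence

# ---------------------------------------------------------------------------
# clade-structured MSA


@dataclass
class MsaSimConfig:
    """Configuration of the clade-structured alignment generator.

    clades: (label, n_sequences) pairs; the first sequence of the first
      clade is the reference.  The reference clade should have >= 2
      members so the reference is never spuriously unique outside the
      planted columns.
    length: number of core (pre-indel) columns.
    clade_divergence_prob: per column, probability that a clade's profile
      substitutes the root residue (independent per clade).
    within_clade_sub_prob: per sequence and column, probability of a
      random substitution away from the clade profile (not applied to
      planted columns, which carry the exact planted signal).
    planted_unique: (core column, reference residue) pairs; all other
      sequences share one common residue there (the alphabetically
      earliest non-reference residue).  Exact truth recovery assumes the
      reference residue is not 'A' when the reference clade has exactly
      two members (an 'A' reference would win the consensus tie-break and
      make the column look clade-discriminating).
    planted_discriminating: (core column, {clade: residue}) pairs; every
      clade is uniform at its residue and the reference gets a residue
      absent from all clades, so these columns are also reference-unique
      (candidate sites by construction).
    indel_prob: per core column, probability of inserting one extra
      column after it in which only one non-reference clade has residues;
      the reference is gapped there, so residue positions fall behind
      column indices.
    """

    clades: list[tuple[str, int]]
    length: int
    seed: int
    clade_divergence_prob: float = 0.3
    within_clade_sub_prob: float = 0.0
    planted_unique: list[tuple[int, str]] = field(default_factory=list)
    planted_discriminating: list[tuple[int, dict[str, str]]] = field(default_factory=list)
    indel_prob: float = 0.0

    def __post_init__(self):
        if not self.clades or any(n < 1 for _, n in self.clades):
            raise DataError("each clade needs >= 1 sequence")
        for p in (self.clade_divergence_prob, self.within_clade_sub_prob, self.indel_prob):
            if not 0.0 <= p <= 1.0:
                raise DataError("probabilities must be in [0, 1]")
        cols_u = {c for c, _ in self.planted_unique}
        cols_d = {c for c, _ in self.planted_discriminating}
        if cols_u & cols_d:
            raise DataError("planted unique and discriminating columns must be disjoint")
        labels = [lab for lab, _ in self.clades]
        for c in cols_u | cols_d:
            if not 1 <= c <= self.length:
                raise DataError(f"planted column {c} outside 1..{self.length}")
        for c, per_clade in self.planted_discriminating:
            missing = set(labels) - set(per_clade)
            if missing:
                raise DataError(f"planted column {c} missing residues for clades {sorted(missing)}")


@dataclass
class MsaTruth:
    """Planted ground truth.  candidate_columns is exact for scans whose
    target clade is not the reference's clade, at zero within-clade
    noise and with a reference clade of >= 2 members."""

    ref_id: str
    unique_columns: list[int]  # post-indel column indices
    discriminating_columns: list[int]
    candidate_columns: list[int]
    reference_positions: dict[int, int]  # post-indel column -> reference position


def _other_residue(rng, exclude) -> str:
    choices = [aa for aa in AMINO_ACIDS if aa not in exclude]
    return choices[rng.integers(len(choices))]


def generate_clade_msa(config: MsaSimConfig) -> tuple[Alignment, MsaTruth]:
    rng = np.random.default_rng(config.seed)
    labels = [lab for lab, _ in config.clades]
    ref_clade = labels[0]
    aa = np.array(list(AMINO_ACIDS))

    root = aa[rng.integers(len(aa), size=config.length)]
    profiles = {}
    for lab in labels:
        prof = root.copy()
        diverge = rng.random(config.length) < config.clade_divergence_prob
        for i in np.nonzero(diverge)[0]:
            prof[i] = _other_residue(rng, {prof[i]})
        profiles[lab] = prof

    ids, clade_of, rows = [], {}, []
    for lab, n in config.clades:
        for k in range(n):
            sid = f"{lab}_{k + 1}"
            ids.append(sid)
            clade_of[sid] = lab
            row = profiles[lab].copy()
            if config.within_clade_sub_prob > 0:
                noisy = rng.random(config.length) < config.within_clade_sub_prob
                for i in np.nonzero(noisy)[0]:
                    row[i] = _other_residue(rng, {row[i]})
            rows.append(row)
    ref_id = f"{ref_clade}_1"
    ref_idx = ids.index(ref_id)

    planted = set()
    for col, ref_res in config.planted_unique:
        # the shared residue is the alphabetically earliest non-reference
        # residue so it wins any consensus tie-break in a 2-member clade,
        # keeping planted-unique columns out of the discriminating set
        common = next(aa_ for aa_ in sorted(AMINO_ACIDS) if aa_ != ref_res)
        for r, row in enumerate(rows):
            row[col - 1] = ref_res if r == ref_idx else common
        planted.add(col)
    for col, per_clade in config.planted_discriminating:
        for r, row in enumerate(rows):
            row[col - 1] = per_clade[clade_of[ids[r]]]
        rows[ref_idx][col - 1] = _other_residue(rng, set(per_clade.values()))
        planted.add(col)
    # keep planted signal exact even under within-clade noise
    # (noise re-applied above would have been overwritten anyway)

    # indel columns: residues only in one randomly chosen non-reference clade
    non_ref = labels[1:]
    insert_after = (
        np.nonzero(rng.random(config.length) < config.indel_prob)[0] + 1
        if (config.indel_prob > 0 and non_ref)
        else np.array([], dtype=int)
    )
    final_rows = [[] for _ in rows]
    core_to_final: dict[int, int] = {}
    final_col = 0
    for core_col in range(1, config.length + 1):
        final_col += 1
        core_to_final[core_col] = final_col
        for r, row in enumerate(rows):
            final_rows[r].append(row[core_col - 1])
        if core_col in insert_after:
            final_col += 1
            lucky = non_ref[rng.integers(len(non_ref))]
            res = _other_residue(rng, set())
            for r in range(len(rows)):
                final_rows[r].append(res if clade_of[ids[r]] == lucky else GAP_CHAR)

    sequences = [
        ProteinSequence(id=sid, residues="".join(final_rows[r]))
        for r, sid in enumerate(ids)
    ]
    alignment = Alignment(sequences=sequences, clade_map=clade_of)

    cmap = alignment.coordinate_map(ref_id)
    unique_cols = sorted(core_to_final[c] for c, _ in config.planted_unique)
    discr_cols = sorted(core_to_final[c] for c, _ in config.planted_discriminating)
    ref_positions = {
        col: cmap.column_to_position(col) for col in unique_cols + discr_cols
    }
    truth = MsaTruth(
        ref_id=ref_id,
        unique_columns=sorted(unique_cols + discr_cols),
        discriminating_columns=discr_cols,
        candidate_columns=discr_cols,
        reference_positions=ref_positions,
    )
    return alignment, truth


# ---------------------------------------------------------------------------
# Michaelis-Menten assay data


@dataclass
class EffectorSpec:
    """Multiplicative action of an effector on the rate law; optionally
    pH-dependent via a {pH: (vmax_factor, km_factor)} override table."""

    vmax_factor: float = 1.0
    km_factor: float = 1.0
    by_ph: dict[float, tuple[float, float]] | None = None

    def factors(self, ph: float) -> tuple[float, float]:
        if self.by_ph is not None and ph in self.by_ph:
            return self.by_ph[ph]
        return self.vmax_factor, self.km_factor


@dataclass
class AssaySimConfig:
    """True kinetic parameters and noise model of the assay generator.

    variants: name -> (Vmax in per-assay units, Km in mM).  Vmax is the
      velocity of the amount of enzyme actually in the cuvette; pair it
      with protein_pmol/protein_ug to express specific activities.
    substrate_mM: titration grid.
    noise_cv: coefficient of variation of multiplicative Gaussian
      replicate noise on velocities.
    effectors: name -> EffectorSpec (mock is implicit).
    """

    variants: dict[str, tuple[float, float]]
    substrate_mM: list[float]
    seed: int
    noise_cv: float = 0.0
    n_replicates: int = 3
    effectors: dict[str, EffectorSpec] = field(default_factory=dict)
    pH: float = 7.3
    temperature_C: float = 30.0
    protein_pmol: float = 4.0
    protein_ug: float = 0.6

    def __post_init__(self):
        for name, (vmax, km) in self.variants.items():
            if vmax <= 0 or km <= 0:
                raise DataError(f"variant {name!r} parameters must be positive")
        if any(s <= 0 for s in self.substrate_mM):
            raise DataError("substrate concentrations must be positive")
        if self.noise_cv < 0 or self.n_replicates < 1:
            raise DataError("noise_cv must be >= 0 and n_replicates >= 1")


def generate_assay_dataset(config: AssaySimConfig) -> tuple[pd.DataFrame, dict]:
    """Long-format rate table (velocity_units column) plus truth record.

    v = fV·Vmax·[S] / (fK·Km + [S]) × (1 + CV·z), z ~ N(0,1) i.i.d. per
    replicate; (fV, fK) are the effector's multiplicative factors (1 for
    mock).  Velocities are clipped at 0 (a negative absorbance slope
    cannot be observed as a negative consumption rate).
    """
    rng = np.random.default_rng(config.seed)
    effectors = {MOCK: EffectorSpec(), **config.effectors}
    rows = []
    truth: dict = {"variants": dict(config.variants), "effector_factors": {}}
    for variant, (vmax, km) in config.variants.items():
        for eff_name, spec in effectors.items():
            fv, fk = spec.factors(config.pH)
            truth["effector_factors"].setdefault(variant, {})[eff_name] = (fv, fk)
            for s in config.substrate_mM:
                mean_v = fv * vmax * s / (fk * km + s)
                for rep in range(1, config.n_replicates + 1):
                    noise = 1.0 + config.noise_cv * rng.standard_normal() if config.noise_cv else 1.0
                    rows.append(
                        {
                            "variant": variant,
                            "effector": eff_name,
                            "effector_mM": 0.0 if eff_name == MOCK else 1.0,
                            "substrate": "PEP",
                            "substrate_mM": s,
                            "pH": config.pH,
                            "temp_C": config.temperature_C,
                            "replicate": rep,
                            "velocity_units": max(mean_v * noise, 0.0),
                        }
                    )
    return pd.DataFrame(rows), truth


def generate_effector_panel(
    mock_velocity: float,
    activity_fractions: dict[str, float],
    n_replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, list[float]], dict]:
    """Fixed-substrate effector panel: replicate velocities per effector.

    Each effector's mean velocity is mock_velocity × its activity
    fraction (e.g. 0.852 for an effector that leaves 85.2% of activity);
    the mock group is included under MOCK.  Truth records the fractions.
    """
    if mock_velocity <= 0:
        raise DataError("mock velocity must be positive")
    rng = np.random.default_rng(seed)
    panel: dict[str, list[float]] = {}
    for name, frac in {MOCK: 1.0, **activity_fractions}.items():
        if frac < 0:
            raise DataError(f"negative activity fraction for {name!r}")
        mean_v = mock_velocity * frac
        noise = (
            1.0 + noise_cv * rng.standard_normal(n_replicates)
            if noise_cv
            else np.ones(n_replicates)
        )
        panel[name] = list(np.maximum(mean_v * noise, 0.0))
    return panel, {"activity_fractions": {MOCK: 1.0, **activity_fractions}}


def generate_trace(
    velocity_units: float,
    condition: Condition | None = None,
    duration_s: float = 120.0,
    n_points: int = 13,
    a0: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    volume_mL: float = 1.0,
    path_cm: float = 1.0,
) -> AssayTrace:
    """Linear A340 trace consistent with a velocity in units (µmol/min):
    slope = -v·ε·path/volume per minute, starting at `a0`."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_s, n_points)
    slope_per_min = -velocity_units * EPSILON_NADH_340 * path_cm / volume_mL
    a = a0 + slope_per_min * (t / 60.0)
    if noise_sd:
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    a = np.clip(a, 0.0, 3.0)
    return AssayTrace(
        time_s=t,
        A340=a,
        condition=condition or Condition(),
        volume_mL=volume_mL,
        path_cm=path_cm,
    )


def generate_activity_profile(
    peak: float,
    width: float,
    grid,
    noise: float = 0.0,
    seed: int = 0,
    axis: str = "pH",
    amplitude: float = 1.0,
) -> ActivityProfile:
    """Gaussian-shaped unimodal activity profile with its maximum at
    `peak` (exact at zero noise when the peak lies on the grid)."""
    grid = np.asarray(grid, dtype=float)
    if peak < grid.min() or peak > grid.max():
        warnings.warn(f"profile peak {peak} lies outside the grid")
    rng = np.random.default_rng(seed)
    mean = amplitude * np.exp(-0.5 * ((grid - peak) / width) ** 2)
    if noise:
        mean = np.maximum(mean * (1.0 + noise * rng.standard_normal(grid.shape)), 0.0)
    return ActivityProfile(axis=axis, grid=grid, mean_activity=mean)
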