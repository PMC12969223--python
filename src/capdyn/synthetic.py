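"""Synthetic task-fMRI studies with planted brain states and trait effects.

The generator emulates a blocked rumination/worry/distraction (RUM/WOR/DIS)
induction experiment: each subject contributes one block per condition, and
each volume (frame) is a noisy, amplitude-jittered copy of one of ``k_true``
latent spatial coactivation patterns.  The latent state sequence follows a
sticky first-order Markov chain whose stationary distribution per
subject-and-condition is planted on occupancy logits, so every downstream
quantity — state maps, per-condition occupancy, trait→dynamics coefficients —
has a known ground truth.

Spatial layout
--------------
The brain is a small ellipsoidal gray-matter mask on a 3-D grid.  Interior
voxels (mask minus its one-voxel boundary shell) are partitioned into seven
contiguous parcels that play the role of a seven-network reference
parcellation.  Each non-artifact latent state is the smoothed, z-scored
indicator of one parcel, so its "network" identity is known; one optional
state lives on the boundary shell and mimics the motion/susceptibility
artifact pattern that frame-wise clustering studies routinely recover and
discard.  Disjoint parcels keep pairwise map correlations far below the
identifiability ceiling.

Trait link
----------
Per-subject occupancy weights are ``softmax(base + condition boost +
b_rnt*rnt + b_neu*neu + b_int*rnt*neu)`` over states, applied in the
configured conditions (by default the two repetitive-negative-thinking
inductions, RUM and WOR, but not DIS).  The softmax keeps weights on the
probability simplex for any coefficient values; on the log-odds scale
(relative to a state with no trait effect) the planted coefficients are
exactly linear and hence recoverable by ordinary least squares.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans

from .errors import ConfigurationError

CONDITIONS = ("RUM", "WOR", "DIS")

#: Seven-network names in the order used for parcel labels 1..7.
NETWORKS = ("Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default")

#: Networks assigned to non-artifact states, in state order.  The first
#: state is default-mode-like and is the one carrying trait effects in the
#: default configuration.
_STATE_NETWORK_ORDER = ("Default", "Cont", "SalVentAttn", "Vis", "SomMot", "DorsAttn", "Limbic")


@dataclass(frozen=True)
class TraitEffects:
    """Planted coefficients on one state's occupancy logit."""

    state: int
    b_rnt: float = 0.0
    b_neu: float = 0.0
    b_interaction: float = 0.0


@dataclass(frozen=True)
class StudyConfig:
    """Full specification of a synthetic study.

    Defaults give the desk-scale design: 40 subjects, three 120-frame
    condition blocks each, ~2,000 gray-matter voxels, five latent states of
    which the last is an edge artifact.
    """

    n_subjects: int = 40
    frames_per_block: int = 120
    grid: tuple[int, int, int] = (19, 19, 15)
    k_true: int = 5
    include_artifact_state: bool = True
    noise_sd: float = 0.5
    amplitude_sd: float = 0.1          # lognormal sigma of per-frame amplitude
    stickiness: float = 0.5            # Markov self-transition mixing weight
    smooth_sigma: float = 1.0          # voxels, spatial smoothing of state maps
    max_pairwise_corr: float = 0.3     # identifiability ceiling for state maps
    base_logits: tuple[float, ...] | None = None
    condition_boost: dict[str, dict[int, float]] | None = None
    trait_effects: tuple[TraitEffects, ...] = (TraitEffects(state=0, b_rnt=0.35, b_neu=0.0, b_interaction=-0.45),)
    trait_effect_conditions: tuple[str, ...] = ("RUM", "WOR")
    trait_corr: float = 0.5            # correlation between rnt and neu scores
    female_fraction: float = 0.7182
    age_mean: float = 23.42
    age_sd: float = 4.03
    voxel_size_mm: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.k_true < 2:
            raise ConfigurationError("k_true must be at least 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0 <= self.stickiness < 1:
            raise ConfigurationError("stickiness must lie in [0, 1)")
        n_network_states = self.k_true - int(self.include_artifact_state)
        if n_network_states > len(NETWORKS):
            raise ConfigurationError(
                f"cannot embed {n_network_states} network states in a "
                f"{len(NETWORKS)}-network parcellation"
            )
        for eff in self.trait_effects:
            if not 0 <= eff.state < self.k_true:
                raise ConfigurationError(f"trait effect refers to unknown state {eff.state}")

    @property
    def artifact_state_id(self) -> int | None:
        return self.k_true - 1 if self.include_artifact_state else None

    def default_base_logits(self) -> np.ndarray:
        if self.base_logits is not None:
            logits = np.asarray(self.base_logits, dtype=float)
            if logits.shape != (self.k_true,):
                raise ConfigurationError("base_logits must have length k_true")
            return logits
        logits = np.zeros(self.k_true)
        if self.artifact_state_id is not None:
            logits[self.artifact_state_id] = -1.0   # artifact frames are rarer
        return logits

    def default_condition_boost(self) -> dict[str, np.ndarray]:
        """Per-condition additive logit offsets (condition-dependent occupancy)."""
        boosts = {c: np.zeros(self.k_true) for c in CONDITIONS}
        if self.condition_boost is not None:
            for cond, entries in self.condition_boost.items():
                for state, value in entries.items():
                    boosts[cond][state] = value
            return boosts
        # Default design: the DMN-like state 0 is favored during the RNT
        # inductions; a control state is favored during distraction.
        boosts["RUM"][0] = 0.4
        boosts["WOR"][0] = 0.4
        if self.k_true >= 2:
            boosts["DIS"][1] = 0.4
        return boosts


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    config: StudyConfig
    state_maps: np.ndarray               # (k_true, n_voxels) unitless activation
    state_networks: list[str | None]     # network name per state, None for artifact
    occupancy: pd.DataFrame              # subject, condition, state, weight
    state_sequences: dict[tuple[str, str], np.ndarray]   # (subject, condition) -> labels
    mask_voxel_ids: np.ndarray           # flat C-order indices into the grid
    amplitudes: dict[tuple[str, str], np.ndarray]

    @property
    def k_true(self) -> int:
        return self.config.k_true

    @property
    def artifact_state_id(self) -> int | None:
        return self.config.artifact_state_id

    def occupancy_wide(self, condition: str) -> pd.DataFrame:
        """Planted weights as subjects x states for one condition."""
        sub = self.occupancy[self.occupancy["condition"] == condition]
        return sub.pivot(index="subject", columns="state", values="weight")


@dataclass
class SyntheticStudy:
    """In-memory bundle of a complete simulated study."""

    images: dict[str, nib.Nifti1Image]
    timing: pd.DataFrame
    mask_img: nib.Nifti1Image
    atlas_img: nib.Nifti1Image
    atlas_lookup: pd.DataFrame
    phenotypes: pd.DataFrame
    qc: pd.DataFrame
    truth: GroundTruth

    def save(self, outdir: str | Path) -> None:
        """Write NIfTI images, TSV tables and a ground-truth JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for subject, img in self.images.items():
            nib.save(img, outdir / f"{subject}_bold.nii")
        nib.save(self.mask_img, outdir / "mask.nii")
        nib.save(self.atlas_img, outdir / "atlas.nii")
        self.timing.to_csv(outdir / "timing.tsv", sep="\t", index=False)
        self.atlas_lookup.to_csv(outdir / "atlas_lookup.tsv", sep="\t", index=False)
        self.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
        self.qc.to_csv(outdir / "qc_roster.tsv", sep="\t", index=False)
        sidecar = {
            "config": _config_to_json(self.truth.config),
            "state_networks": self.truth.state_networks,
            "artifact_state_id": self.truth.artifact_state_id,
            "mask_voxel_ids": self.truth.mask_voxel_ids.tolist(),
        }
        (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
        np.savez_compressed(
            outdir / "ground_truth_arrays.npz",
            state_maps=self.truth.state_maps,
            **{f"seq_{s}_{c}": v for (s, c), v in self.truth.state_sequences.items()},
        )


def _config_to_json(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)
    d["trait_effects"] = [dataclasses.asdict(e) for e in config.trait_effects]
    return d


def ellipsoid_mask(grid: tuple[int, int, int]) -> np.ndarray:
    """Binary ellipsoid filling the grid with a one-voxel margin."""
    center = (np.asarray(grid) - 1) / 2
    semi = (np.asarray(grid) - 2) / 2
    coords = np.indices(grid).astype(float)
    dist = sum(((coords[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return dist <= 1.0


def boundary_shell(mask: np.ndarray) -> np.ndarray:
    """One-voxel-thick outer shell of a binary mask (6-connectivity)."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return mask & ~eroded


def sample_state_sequence(weights: np.ndarray, length: int, stickiness: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Sticky Markov chain with stationary distribution ``weights``.

    Transition kernel ``P(j|i) = stickiness * [i == j] + (1 - stickiness) * w_j``;
    its stationary distribution is exactly ``w`` for any stickiness in [0, 1).
    """
    weights = np.asarray(weights, dtype=float)
    k = weights.size
    states = np.empty(length, dtype=np.int64)
    states[0] = rng.choice(k, p=weights)
    stay = rng.random(length - 1) < stickiness
    jumps = rng.choice(k, size=length - 1, p=weights)
    for t in range(1, length):
        states[t] = states[t - 1] if stay[t - 1] else jumps[t - 1]
    return states


def _build_parcels(interior_coords: np.ndarray, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=len(NETWORKS), n_init=4, random_state=seed)
    return km.fit_predict(interior_coords.astype(float))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ConfigurationError("degenerate (constant) state map")
    return (v - v.mean()) / sd


def build_state_maps(config: StudyConfig, mask: np.ndarray) -> tuple[np.ndarray, list[str | None], np.ndarray]:
    """Construct latent state maps on the masked grid.

    Returns (state_maps, state_networks, atlas_labels_3d) where atlas labels
    are 1..7 over interior voxels and 0 elsewhere.
    """
    shell = boundary_shell(mask)
    interior = mask & ~shell
    n_interior = int(interior.sum())
    n_states = config.k_true - int(config.include_artifact_state)
    if n_interior < len(NETWORKS) * max(2, config.k_true):
        raise ConfigurationError(
            f"grid {config.grid} has only {n_interior} interior voxels; too small "
            f"to embed {config.k_true} non-overlapping state patterns"
        )
    interior_coords = np.argwhere(interior)
    parcels = _build_parcels(interior_coords, seed=config.seed)

    atlas = np.zeros(mask.shape, dtype=np.int16)
    atlas[tuple(interior_coords.T)] = parcels + 1

    mask_flat = mask.ravel()
    maps = []
    networks: list[str | None] = []
    for s in range(n_states):
        network = _STATE_NETWORK_ORDER[s]
        label = NETWORKS.index(network) + 1
        vol = (atlas == label).astype(float)
        if config.smooth_sigma > 0:
            vol = ndimage.gaussian_filter(vol, sigma=config.smooth_sigma)
        vol[~mask] = 0.0
        maps.append(_zscore(vol.ravel()[mask_flat]))
        networks.append(network)
    if config.include_artifact_state:
        vol = shell.astype(float)
        maps.append(_zscore(vol.ravel()[mask_flat]))
        networks.append(None)
    state_maps = np.stack(maps)

    # Gram-Schmidt-style decorrelation: deflate later maps against earlier
    # ones until every pairwise |r| sits below the identifiability ceiling.
    target = 0.9 * config.max_pairwise_corr
    for _ in range(20):
        corr = np.corrcoef(state_maps)
        off = np.abs(corr - np.eye(config.k_true))
        if off.max() < config.max_pairwise_corr:
            break
        i, j = np.unravel_index(off.argmax(), off.shape)
        lo, hi = min(i, j), max(i, j)
        r = corr[lo, hi]
        shrink = 1.0 - target / abs(r)
        state_maps[hi] = _zscore(state_maps[hi] - shrink * r * state_maps[lo])
    corr = np.corrcoef(state_maps)
    off = np.abs(corr[~np.eye(config.k_true, dtype=bool)])
    if off.max() >= config.max_pairwise_corr:
        raise ConfigurationError(
            f"state maps are not identifiable: max pairwise |r| = {off.max():.3f} "
            f">= ceiling {config.max_pairwise_corr}"
        )
    return state_maps, networks, atlas


def planted_occupancy(config: StudyConfig, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per subject-condition stationary weights from the planted logit model.

    Trait scores enter the logits only in ``trait_effect_conditions``; the
    rnt and neu columns of ``phenotypes`` are used as-is (the generator
    produces them standardized).
    """
    base = config.default_base_logits()
    boosts = config.default_condition_boost()
    records = []
    for row in phenotypes.itertuples(index=False):
        for cond in CONDITIONS:
            eta = base + boosts[cond]
            if cond in config.trait_effect_conditions:
                for eff in config.trait_effects:
                    eta = eta.copy()
                    eta[eff.state] += (eff.b_rnt * row.rnt + eff.b_neu * row.neu
                                       + eff.b_interaction * row.rnt * row.neu)
            w = np.exp(eta - eta.max())
            w /= w.sum()
            for s in range(config.k_true):
                records.append((row.subject, cond, s, w[s]))
    return pd.DataFrame(records, columns=["subject", "condition", "state", "weight"])


def _simulate_phenotypes(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    cov = np.array([[1.0, config.trait_corr], [config.trait_corr, 1.0]])
    traits = rng.multivariate_normal([0.0, 0.0], cov, size=config.n_subjects)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, config.n_subjects), 18, 45)
    sex = np.where(rng.random(config.n_subjects) < config.female_fraction, "F", "M")
    subjects = [f"sub-{i + 1:03d}" for i in range(config.n_subjects)]
    return pd.DataFrame({
        "subject": subjects,
        "rnt": traits[:, 0],
        "neu": traits[:, 1],
        "age": np.round(age, 2),
        "sex": sex,
    })


def simulate_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study with known ground truth.

    Identical configurations (including the seed) produce bit-identical
    outputs.  Blocks are laid out consecutively per subject; the two RNT
    inductions are presented in randomized order with distraction always
    last, and the timing table uses half-open 0-based volume intervals.
    """
    if config is None:
        config = StudyConfig()
    rng = np.random.default_rng(config.seed)

    mask = ellipsoid_mask(config.grid)
    state_maps, state_networks, atlas = build_state_maps(config, mask)
    mask_voxel_ids = np.flatnonzero(mask.ravel())
    n_voxels = mask_voxel_ids.size

    phenotypes = _simulate_phenotypes(config, rng)
    occupancy = planted_occupancy(config, phenotypes)
    occ_lookup = {(r.subject, r.condition): np.empty(config.k_true) for r in occupancy.itertuples()}
    for r in occupancy.itertuples():
        occ_lookup[(r.subject, r.condition)][r.state] = r.weight

    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    mask_img = nib.Nifti1Image(mask.astype(np.uint8), affine)
    atlas_img = nib.Nifti1Image(atlas, affine)
    atlas_lookup = pd.DataFrame({"label": np.arange(1, len(NETWORKS) + 1), "network": NETWORKS})

    fpb = config.frames_per_block
    images: dict[str, nib.Nifti1Image] = {}
    timing_rows = []
    sequences: dict[tuple[str, str], np.ndarray] = {}
    amplitudes: dict[tuple[str, str], np.ndarray] = {}
    for subject in phenotypes["subject"]:
        rnt_order = ["RUM", "WOR"] if rng.random() < 0.5 else ["WOR", "RUM"]
        cond_order = rnt_order + ["DIS"]
        vol4d = np.zeros(config.grid + (3 * fpb,), dtype=np.float32)
        flat = vol4d.reshape(-1, 3 * fpb)
        for b, cond in enumerate(cond_order):
            start, end = b * fpb, (b + 1) * fpb
            timing_rows.append((subject, cond, start, end))
            seq = sample_state_sequence(occ_lookup[(subject, cond)], fpb,
                                        config.stickiness, rng)
            amp = np.exp(rng.normal(0.0, config.amplitude_sd, fpb))
            frames = amp[:, None] * state_maps[seq]
            if config.noise_sd > 0:
                frames = frames + rng.normal(0.0, config.noise_sd, frames.shape)
            flat[mask_voxel_ids, start:end] = frames.T.astype(np.float32)
            sequences[(subject, cond)] = seq
            amplitudes[(subject, cond)] = amp
        images[subject] = nib.Nifti1Image(vol4d, affine)

    timing = pd.DataFrame(timing_rows, columns=["subject", "condition", "start_volume", "end_volume"])
    qc = pd.DataFrame({
        "subject": phenotypes["subject"],
        "mean_abs_motion": np.round(rng.uniform(0.05, 1.2, config.n_subjects), 3),
        "artifact_flag": False,
        "attention_correct": 3,
    })
    truth = GroundTruth(
        config=config,
        state_maps=state_maps,
        state_networks=state_networks,
        occupancy=occupancy,
        state_sequences=sequences,
        mask_voxel_ids=mask_voxel_ids,
        amplitudes=amplitudes,
    )
    return SyntheticStudy(images=images, timing=timing, mask_img=mask_img,
                          atlas_img=atlas_img, atlas_lookup=atlas_lookup,
                          phenotypes=phenotypes, qc=qc, truth=truth)


def make_qc_roster(n_total: int, n_motion_fail: int, n_attention_fail: int,
                   seed: int, n_artifact_fail: int = 0) -> pd.DataFrame:
    """QC roster with exact, disjoint counts of motion, artifact and
    attention failures; everyone else passes all rules."""
    counts = (n_total, n_motion_fail, n_attention_fail, n_artifact_fail)
    if any(c < 0 for c in counts):
        raise ConfigurationError("roster counts must be non-negative")
    if n_motion_fail + n_attention_fail + n_artifact_fail > n_total:
        raise ConfigurationError("failure counts exceed roster size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_total)
    motion_ids = set(order[:n_motion_fail])
    artifact_ids = set(order[n_motion_fail:n_motion_fail + n_artifact_fail])
    attention_ids = set(order[n_motion_fail + n_artifact_fail:
                              n_motion_fail + n_artifact_fail + n_attention_fail])
    rows = []
    for i in range(n_total):
        subject = f"sub-{i + 1:03d}"
        if i in motion_ids:
            motion = round(float(rng.uniform(4.5, 9.0)), 3)
        else:
            motion = round(float(rng.uniform(0.05, 1.5)), 3)
        attention = int(rng.integers(0, 2)) if i in attention_ids else int(rng.integers(2, 4))
        rows.append((subject, motion, i in artifact_ids, attention))
    return pd.DataFrame(rows, columns=["subject", "mean_abs_motion", "artifact_flag", "attention_correct"])
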