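"""Synthetic developmental cohorts with planted connectome ground truth.

The generator emulates the features of a developmental functional-MRI
cohort that the analysis stages must recover:

* a sensory-to-DMN principal axis ``g0`` over the parcels, whose
  expression in connectivity *expands* linearly with age in typically
  developing (TD) subjects;
* an autism (ASD) group whose expression of the axis is attenuated with an
  inverted-U age profile (largest deficit in childhood, full catch-up at a
  configurable peak age, decline afterwards), plus network-specific
  compression: sensory/attention parcels pulled toward zero in childhood
  and DMN parcels pulled toward zero persistently;
* 7-network modular block structure and symmetric subject noise, generated
  directly in Fisher-z space;
* a mediation chain active in late adolescence: a subject-level latent
  integration factor that decoheres the DMN's gradient loadings and thins
  its within-network edges (raising DMN participation) while degrading the
  subject's hierarchy alignment;
* symptom scores negatively correlated with the planted hierarchy
  alignment.

Everything is deterministic given ``(parameters, seed)``: per-subject
randomness derives from a stable hash of the subject id, so regenerating a
single subject's matrix never depends on cohort order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import NETWORKS, ParcelAtlas
from .connectome import ConnectivityMatrix

#: Base position of each network along the sensory -> DMN axis.
NETWORK_POLES: dict[str, float] = {
    "Visual": -1.2,
    "Somatomotor": -1.0,
    "DorsalAttention": -0.5,
    "VentralAttention": -0.3,
    "Limbic": 0.1,
    "Control": 0.6,
    "DMN": 1.2,
}

#: ASD childhood compression amplitude per network (fraction pulled toward 0).
ASD_CHILDHOOD_COMPRESSION: dict[str, float] = {
    "Somatomotor": 0.22,
    "DorsalAttention": 0.25,
    "VentralAttention": 0.25,
}

ASD_DMN_COMPRESSION: float = 0.12  # persistent across the age range


def template_axis(atlas: ParcelAtlas, spread: float = 0.15) -> np.ndarray:
    """Deterministic sensory->DMN axis ``g0`` for an atlas.

    Each parcel gets its network's pole value plus a small within-network
    linear spread so loadings are not exactly tied.
    """
    g0 = np.empty(atlas.n_parcels)
    for net in NETWORKS:
        idx = atlas.indices(net)
        if idx.size == 1:
            offs = np.array([0.0])
        else:
            offs = np.linspace(-spread, spread, idx.size)
        g0[idx] = NETWORK_POLES[net] + offs
    return g0


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth generative parameters of a synthetic cohort."""

    seed: int = 0
    age_lo: float = 5.0
    age_hi: float = 22.0
    expansion_rate: float = 0.04   # per year; s_TD(age) = 1 + rate*(age - lo)
    asd_peak_age: float = 15.0     # age of full catch-up of the ASD group
    asd_curvature: float = 0.002       # attenuation curvature before the peak
    asd_curvature_late: float = 0.004  # steeper decline after the peak
    asd_floor: float = 0.4
    grad_weight: float = 0.35
    module_strength: float = 0.25
    grad_jitter: float = 0.0       # per-subject SD of the gradient weight
    module_jitter: float = 0.25    # per-subject, per-network SD of module strength
    hub_edge_frac: float = 0.008   # sparse random strong long-range edges
    hub_edge_strength: float = 0.9
    noise_sd: float = 0.25     # subject noise SD at the youngest age
    noise_decay: float = 0.0   # optional fractional decay across the range
    childhood_compression: dict = field(
        default_factory=lambda: dict(ASD_CHILDHOOD_COMPRESSION))
    dmn_compression: float = ASD_DMN_COMPRESSION
    mediation_onset_age: float = 16.0
    mediation_u_shift: float = 0.6   # ASD mean of the latent integration factor
    mediation_u_sd: float = 0.35
    deseg_within_weight: float = 0.5   # within-DMN edge loss per unit latent
    deseg_compensation: float = 0.15   # sensory within-module edge gain
    latent_axis_compression: float = 0.12  # extra DMN compression per unit latent
    site_offsets: tuple[float, ...] = ()

    def s_td(self, age):
        """TD expansion scale; strictly increasing over the age range."""
        return 1.0 + self.expansion_rate * (np.asarray(age, float) - self.age_lo)

    def d_asd(self, age):
        """ASD multiplicative attenuation; inverted U peaking at 1.

        The post-peak branch is steeper than the pre-peak one: the decline
        after catch-up is more pronounced than the residual global deficit
        in childhood (where network compression does most of the work).
        """
        age = np.asarray(age, float)
        curv = np.where(age <= self.asd_peak_age, self.asd_curvature,
                        self.asd_curvature_late)
        return np.maximum(self.asd_floor,
                          1.0 - curv * (age - self.asd_peak_age) ** 2)

    def childhood_weight(self, age):
        """Compression ramp: 1 at the range start, 0 from the catch-up age on.

        Square-root shape: the approach to full catch-up stays steep close
        to the peak age, so the group's trajectory rises identifiably into
        the peak instead of flattening years earlier.
        """
        span = self.asd_peak_age - self.age_lo
        t = np.clip((self.asd_peak_age - age) / span, 0.0, 1.0)
        return float(np.sqrt(t))

    def latent_ramp(self, age) -> float:
        """Smooth onset of the late-adolescent latent effect (2-year ramp)."""
        return float(np.clip((float(age) - self.mediation_onset_age) / 2.0,
                             0.0, 1.0))

    def noise_level(self, age, group: str) -> float:
        """Subject noise SD: decays with age in TD (developmental
        convergence toward the norm); constant in ASD at the level TD
        reaches at the catch-up age, so the groups meet there."""
        # same decay in both groups (plateau at the catch-up age): group
        # contrasts are carried by the planted compression/attenuation and
        # latent terms, never by noise asymmetry
        span = self.age_hi - self.age_lo
        t = (min(float(age), self.asd_peak_age) - self.age_lo) / span
        return self.noise_sd * (1.0 - self.noise_decay * np.clip(t, 0.0, 1.0))

    def subject_rng(self, subject_id: str) -> np.random.Generator:
        tag = zlib.crc32(str(subject_id).encode()) & 0x7FFFFFFF
        return np.random.default_rng([self.seed, tag])

    def latent_u(self, subject_id: str, age: float, group: str) -> float:
        """Latent integration factor driving the late-adolescent mediation."""
        ramp = self.latent_ramp(age)
        if ramp == 0.0:
            return 0.0
        rng = np.random.default_rng([self.seed, zlib.crc32(str(subject_id).encode())
                                     & 0x7FFFFFFF, 11])
        loc = self.mediation_u_shift if group == "ASD" else 0.0
        return ramp * float(max(0.0, rng.normal(loc, self.mediation_u_sd)))

    def subject_axis(self, age: float, group: str, atlas: ParcelAtlas,
                     u: float = 0.0) -> np.ndarray:
        """Direction of the subject's gradient axis (before global scale).

        ASD subjects carry the network compressions: sensory/attention
        loadings pulled toward zero in childhood, DMN loadings mildly
        compressed throughout. The latent integration factor ``u``
        compresses the DMN end further, coupling the late-adolescent
        hierarchy decline to the same subjects whose DMN desegregates.
        """
        g = template_axis(atlas).copy()
        if group == "ASD":
            w = self.childhood_weight(age)
            for net, amp in self.childhood_compression.items():
                g[atlas.indices(net)] *= 1.0 - amp * w
            g[atlas.indices("DMN")] *= 1.0 - self.dmn_compression
        if u > 0 and self.latent_axis_compression:
            g[atlas.indices("DMN")] *= max(0.2, 1.0 -
                                           self.latent_axis_compression * u)
        return g

    @staticmethod
    def dmn_swap_parcels(atlas: ParcelAtlas) -> np.ndarray:
        """Deterministic half of the DMN parcels carrying the edge swap."""
        return atlas.indices("DMN")[1::2]

    def subject_scale(self, age: float, group: str) -> float:
        """Global expression scale of the gradient term."""
        s = float(self.s_td(age))
        if group == "ASD":
            s *= float(self.d_asd(age))
        return s

    def planted_alignment(self, subject_id: str, age: float, group: str,
                          atlas: ParcelAtlas) -> float:
        """Generator-level proxy of the subject's hierarchy alignment.

        Cosine of the subject's axis against ``g0``, discounted by the
        gradient term's share of the signal (weaker expression leaves more
        of the estimated gradient to noise and module structure) and by
        the latent desegregation (which blurs the DMN end of the axis).
        """
        g0 = template_axis(atlas)
        u = self.latent_u(subject_id, age, group)
        g = self.subject_axis(age, group, atlas, u)
        cos = float(g @ g0 / (np.linalg.norm(g) * np.linalg.norm(g0)))
        s = self.subject_scale(age, group)
        nsd = self.noise_level(age, group)
        snr = s / (s + nsd + self.module_strength)
        base = 1.0 / (1.0 + self.module_strength)
        return cos * snr / base


def simulate_cohort(n_td: int, n_asd: int, truth: SimTruth,
                    age_distribution: str = "uniform",
                    n_sites: int = 1, seed: int | None = None) -> pd.DataFrame:
    """Phenotype table for a synthetic cohort.

    Ages are uniform on the configured range by default; the "skewed"
    option concentrates sampling in childhood (sparse older subjects, as
    in typical open autism cohorts). Sexes are balanced in expectation.
    """
    if n_td < 0 or n_asd < 0:
        raise ValueError("group sizes must be nonnegative")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([seed, 1])
    rows = []
    for group, n, prefix in (("TD", n_td, "td"), ("ASD", n_asd, "asd")):
        for i in range(n):
            if age_distribution == "uniform":
                age = rng.uniform(truth.age_lo, truth.age_hi)
            elif age_distribution == "skewed":
                # beta(1.2, 2.2): dense childhood sampling, sparse young adults
                age = truth.age_lo + rng.beta(1.2, 2.2) * (truth.age_hi - truth.age_lo)
            else:
                raise ValueError(f"unknown age distribution: {age_distribution}")
            rows.append({
                "subject_id": f"{prefix}-{i + 1:04d}",
                "age": float(age),
                "sex": "female" if rng.random() < 0.5 else "male",
                "group": group,
                "site": f"site{int(rng.integers(n_sites)) + 1}",
            })
    cols = ["subject_id", "age", "sex", "group", "site"]
    return pd.DataFrame(rows, columns=cols)


def simulate_connectivity(row, truth: SimTruth, atlas: ParcelAtlas) -> ConnectivityMatrix:
    """One subject's Fisher-z connectivity matrix.

    Weighted sum of (a) the rank-1 outer product of the subject's scaled
    gradient axis, (b) a within-network block term, (c) the late-adolescent
    DMN bridge term when active, and (d) symmetric Gaussian noise. The
    diagonal is zero and the matrix exactly symmetric.
    """
    for key in ("subject_id", "age", "group"):
        if key not in row or row[key] is None:
            raise ValueError(f"subject row lacks {key}")
    sid, age, group = str(row["subject_id"]), float(row["age"]), str(row["group"])
    P = atlas.n_parcels
    u = truth.latent_u(sid, age, group)
    g = truth.subject_axis(age, group, atlas, u)
    s = truth.subject_scale(age, group)
    gs = s * g
    W = truth.grad_weight * np.outer(gs, gs)

    # per-subject heterogeneity: individual gradient expression and
    # network cohesion vary, giving every network a genuine participation
    # distribution in the reference population
    jrng = np.random.default_rng([truth.seed,
                                  zlib.crc32(sid.encode()) & 0x7FFFFFFF, 13])
    if truth.grad_jitter:
        W *= max(0.2, 1.0 + truth.grad_jitter * jrng.standard_normal())
    if truth.module_strength:
        modules = atlas.module_index()
        net_strength = truth.module_strength * np.clip(
            1.0 + truth.module_jitter * jrng.standard_normal(len(NETWORKS)),
            0.2, None)
        block = net_strength[modules[:, None]] * (
            modules[:, None] == modules[None, :])
        W += block

    if u > 0 and truth.deseg_within_weight:
        # DMN desegregation: half the DMN parcels lose within-network
        # connectivity (their participation rises and the DMN end of the
        # estimated gradient blurs). Because the binary topology graph
        # keeps a fixed global edge quota, the freed quota is absorbed by
        # strengthening sensory within-module edges — positions where
        # extra edges leave the sensory networks' own participation flat —
        # so segregation elsewhere is preserved by construction.
        dmn = atlas.indices("DMN")
        swap = truth.dmn_swap_parcels(atlas)
        within = np.zeros((P, P))
        within[np.ix_(swap, dmn)] = 1.0
        within[np.ix_(dmn, swap)] = 1.0
        np.fill_diagonal(within, 0.0)
        W -= truth.deseg_within_weight * u * within
        if truth.deseg_compensation:
            sink = np.zeros((P, P))
            for net in ("Visual", "Somatomotor"):
                idx = atlas.indices(net)
                sink[np.ix_(idx, idx)] = 1.0
            np.fill_diagonal(sink, 0.0)
            W += truth.deseg_compensation * u * sink

    if truth.hub_edge_frac:
        # sparse subject-specific long-range hub edges: individual
        # variation in cross-network integration present in any real
        # cohort, giving every network a nondegenerate participation
        # distribution
        iu, ju = np.triu_indices(P, 1)
        n_extra = int(round(truth.hub_edge_frac * len(iu)))
        pick = jrng.choice(len(iu), size=n_extra, replace=False)
        extra = np.zeros((P, P))
        extra[iu[pick], ju[pick]] = truth.hub_edge_strength
        W += extra + extra.T

    nsd = truth.noise_level(age, group)
    if nsd > 0:
        rng = truth.subject_rng(sid)
        noise = rng.normal(0.0, nsd, size=(P, P))
        W += np.triu(noise, 1) + np.triu(noise, 1).T

    if truth.site_offsets and "site" in row:
        site_idx = int(str(row["site"]).removeprefix("site")) - 1
        if site_idx < len(truth.site_offsets):
            off = truth.site_offsets[site_idx]
            W += off * (1.0 - np.eye(P))

    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(values=W)


def simulate_timeseries(connectivity: ConnectivityMatrix | np.ndarray, T: int,
                        seed: int = 0) -> np.ndarray:
    """Sample a T x P BOLD-like time series whose correlation matches a target.

    The Fisher-z connectivity is mapped back to correlation space (tanh),
    shrunk toward the identity with the smallest weight making it positive
    definite, and sampled as zero-mean multivariate Gaussian draws. The
    empirical correlation converges to the (shrunken) target as T grows.
    """
    if T < 2:
        raise ValueError(f"need at least 2 timepoints, got {T}")
    z = connectivity.values if isinstance(connectivity, ConnectivityMatrix) \
        else np.asarray(connectivity, float)
    R = np.tanh(z)
    np.fill_diagonal(R, 1.0)
    lam_min = float(np.linalg.eigvalsh(R).min())
    eps = 1e-6
    if lam_min < eps:
        w = (eps - lam_min) / (1.0 - lam_min)
        R = (1.0 - w) * R + w * np.eye(len(R))
    L = np.linalg.cholesky(R)
    rng = np.random.default_rng(seed)
    return rng.standard_normal((T, len(R))) @ L.T


def simulate_symptoms(cohort: pd.DataFrame, hierarchy_truth, rho: float,
                      seed: int = 0, subscore_noise: float = 0.3) -> pd.DataFrame:
    """Add SRS-like symptom columns correlated with hierarchy alignment.

    The total score has target correlation ``rho`` (typically negative:
    stronger deviation from the normative hierarchy, higher severity) with
    the planted alignment; the five subscores are noisy copies of the
    total. Scores are reported on a T-score-like scale (60 +/- 15).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    h = np.asarray(hierarchy_truth, dtype=float)
    if len(h) != len(cohort):
        raise ValueError("hierarchy_truth length must match the cohort")
    rng = np.random.default_rng([seed, 3])
    zh = (h - h.mean()) / h.std() if h.std() > 0 else np.zeros_like(h)
    eps = rng.standard_normal(len(h))
    total_z = rho * zh + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
    out = cohort.copy()
    out["srs_total"] = 60.0 + 15.0 * total_z
    for sub in ("awareness", "cognition", "communication", "motivation",
                "mannerisms"):
        noise = rng.standard_normal(len(h)) * subscore_noise
        out[f"srs_{sub}"] = 60.0 + 15.0 * (total_z + noise)
    return out


def simulate_dataset(n_td: int, n_asd: int, truth: SimTruth, atlas: ParcelAtlas,
                     age_distribution: str = "uniform",
                     symptom_rho: float | None = -0.4):
    """Cohort table + per-subject connectivity, in one deterministic call."""
    cohort = simulate_cohort(n_td, n_asd, truth, age_distribution)
    matrices = {
        row.subject_id: simulate_connectivity(row._asdict(), truth, atlas)
        for row in cohort.itertuples(index=False)
    }
    if symptom_rho is not None:
        truth_align = np.array([
            truth.planted_alignment(r.subject_id, r.age, r.group, atlas)
            for r in cohort.itertuples(index=False)
        ])
        cohort = simulate_symptoms(cohort, truth_align, symptom_rho,
                                   seed=truth.seed)
    return cohort, matrices
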