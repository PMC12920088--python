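"""Synthetic cortical vascular trees.

The generated geometry mirrors the organisation of the mouse cortical
microvasculature as seen in a coronal ultrasound slice: penetrating
arterioles descend from the surface (flow with ``v_z > 0``), continue below
the ~400 µm depth threshold as arteriole–capillary-transition (ACT)
segments — the pericyte-covered first capillary branches — with some oblique
side branches, while ascending venules drain upward (``v_z < 0``).

Phenotype knobs reproduce the vascular alterations of pericyte dysfunction:
arteriolar/ACT dilation, reduced ACT blood speed, sinusoidal centerline
tortuosity, and blunted/delayed stimulus-evoked flux (the latter consumed by
:mod:`fulmkit.synth.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VesselSegmentSpec", "PhenotypeParams", "TreeLayout", "build_vessel_tree"]


@dataclass
class VesselSegmentSpec:
    """One vessel segment: polyline centerline plus flow/geometry attributes.

    The centerline is stored in flow order (a bubble enters at the first
    vertex); ``flow_direction`` is kept for completeness and is +1 in that
    convention.
    """

    id: int
    vessel_class: str  # pial | penetrating_arteriole | ACT | capillary | venule
    centerline: np.ndarray  # (n, 2) of (x, z) µm, flow order
    diameter: float  # µm
    mean_speed: float  # mm/s
    flow_direction: int = 1
    parent: int | None = None
    bubble_rate: float = 0.0  # MBs/s entering at baseline
    activated: bool = False  # stimulation modulates flux in this segment

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.diameter <= 0:
            raise ValueError(f"segment {self.id}: diameter must be > 0")
        if self.mean_speed < 0 or self.bubble_rate < 0:
            raise ValueError(f"segment {self.id}: speed and rate must be >= 0")

    @property
    def length_um(self) -> float:
        steps = np.diff(self.centerline, axis=0)
        return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))

    def mean_vz_sign(self) -> float:
        dz = self.centerline[-1, 1] - self.centerline[0, 1]
        return float(np.sign(dz))


@dataclass(frozen=True)
class PhenotypeParams:
    """Phenotype knobs; defaults are the healthy control (all neutral)."""

    dilation_factor: float = 1.0
    speed_factor_arteriole: float = 1.0
    speed_factor_act: float = 1.0
    tortuosity_amplitude: float = 0.0  # µm
    tortuosity_wavelength: float = 300.0  # µm
    activation_gain: float = 0.5  # fractional flux increase during stimulation
    activation_delay_s: float = 0.0
    activation_rise_s: float = 2.0
    activation_overshoot: bool = False
    overshoot_gain: float = 0.0  # extra fractional gain during the overshoot

    def __post_init__(self) -> None:
        if min(self.dilation_factor, self.speed_factor_arteriole,
               self.speed_factor_act) <= 0:
            raise ValueError("phenotype factors must be > 0")
        if self.activation_delay_s < 0 or self.tortuosity_amplitude < 0:
            raise ValueError("delay and tortuosity amplitude must be >= 0")


CONTROL = PhenotypeParams()


@dataclass(frozen=True)
class TreeLayout:
    """Desk-scale scene layout: counts, depths, diameters, speeds, rates.

    Defaults give a 3 × 3 mm² field with 5 penetrating arterioles (each
    continuing as an ACT trunk below 400 µm), 3 extra oblique ACT branches
    (8 ACT segments in total) and 2 ascending venules.  Baseline bubble
    rates are set so that roughly 10–20 microbubbles are in transit per
    frame — the scaled-down analogue of a continuous-infusion ULM
    acquisition.
    """

    field_width_um: float = 3960.0
    field_depth_um: float = 3080.0
    #: vessels are kept this far from the lateral field edges so the PSF
    #: footprint (4σ ≈ 400 µm) never clips, which would bias localization
    edge_margin_um: float = 420.0
    n_arterioles: int = 5
    n_act_branches: int = 8  # total, including arteriole continuations
    n_venules: int = 2
    n_pial: int = 0
    act_depth_threshold_um: float = 400.0
    act_bottom_um: float = 1400.0
    arteriole_top_um: float = 60.0
    arteriole_diameter_um: float = 28.0
    act_diameter_um: float = 14.0
    venule_diameter_um: float = 36.0
    arteriole_speed_mm_s: float = 8.0
    act_speed_mm_s: float = 3.0
    venule_speed_mm_s: float = 5.0
    arteriole_rate: float = 5.0  # MBs/s
    act_rate: float = 2.0
    venule_rate: float = 4.0
    vertex_spacing_um: float = 20.0
    #: arteriole indices whose subtree (arteriole + ACT descendants) responds
    #: to stimulation
    activated_arterioles: tuple[int, ...] = (1, 2)
    #: classes within an activated subtree that actually carry the flux gain
    activated_classes: tuple[str, ...] = ("penetrating_arteriole", "ACT")


def desk_grid(layout: "TreeLayout | None" = None,
              acq=None) -> "GridSpec":
    """Native GridSpec matching a layout's field of view (desk scene:
    36 × 30 native pixels ≈ 3.96 × 3.08 mm)."""
    from ..config import AcquisitionConfig, GridSpec

    layout = layout or TreeLayout()
    acq = acq or AcquisitionConfig()
    return GridSpec(
        n_x_native=int(np.ceil(layout.field_width_um / 110.0)),
        n_z_native=int(np.ceil(layout.field_depth_um / acq.wavelength_um)),
    )


def _polyline(p0, p1, spacing):
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / spacing)) + 1)
    t = np.linspace(0.0, 1.0, n)
    return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


def _perturb(centerline: np.ndarray, amplitude: float, wavelength: float,
             phase: float) -> np.ndarray:
    """Sinusoidal tortuosity: offset orthogonal to the chord, pinned at the
    first vertex so children attached there stay attached."""
    if amplitude == 0:
        return centerline
    chord = centerline[-1] - centerline[0]
    norm = np.linalg.norm(chord)
    if norm == 0:
        return centerline
    u = chord / norm
    normal = np.array([-u[1], u[0]])
    steps = np.diff(centerline, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(steps[:, 0], steps[:, 1]))])
    offset = amplitude * np.sin(2 * np.pi * s / wavelength + phase)
    offset -= offset[0]
    return centerline + offset[:, None] * normal[None, :]


def build_vessel_tree(
    layout: TreeLayout | None = None,
    phenotype: PhenotypeParams = CONTROL,
    seed: int = 0,
) -> list[VesselSegmentSpec]:
    """Build a deterministic (seeded) vascular tree for one synthetic scene.

    Dilation applies to arteriolar-side vessels (penetrating arterioles and
    ACT segments), matching the dilation phenotype's localisation; venules
    are left unchanged.  Tortuosity perturbs arteriole and ACT-trunk
    centerlines.  Raises ``ValueError`` listing any segment whose geometry
    (including its radius) leaves the field of view.
    """
    layout = layout or TreeLayout()
    rng = np.random.default_rng(seed)
    segments: list[VesselSegmentSpec] = []
    next_id = 0

    def add(seg: VesselSegmentSpec) -> VesselSegmentSpec:
        segments.append(seg)
        return seg

    margin = layout.edge_margin_um
    n_cols = layout.n_arterioles + layout.n_venules
    xs = np.linspace(margin, layout.field_width_um - margin, n_cols)
    xs = xs + rng.uniform(-15, 15, size=n_cols)
    order = rng.permutation(n_cols)
    art_x = np.sort(xs[order[: layout.n_arterioles]])
    ven_x = np.sort(xs[order[layout.n_arterioles:]])

    dil = phenotype.dilation_factor

    if layout.n_pial:
        y = layout.arteriole_top_um * 0.6
        for _ in range(layout.n_pial):
            add(VesselSegmentSpec(
                id=(next_id := next_id + 1) - 1,
                vessel_class="pial",
                centerline=_polyline((margin, y), (layout.field_width_um - margin, y),
                                     layout.vertex_spacing_um),
                diameter=layout.arteriole_diameter_um * 1.5 * dil,
                mean_speed=layout.arteriole_speed_mm_s,
                bubble_rate=layout.arteriole_rate,
            ))

    trunks: list[VesselSegmentSpec] = []
    for i, x in enumerate(art_x):
        activated = i in layout.activated_arterioles
        art = add(VesselSegmentSpec(
            id=(next_id := next_id + 1) - 1,
            vessel_class="penetrating_arteriole",
            centerline=_perturb(
                _polyline((x, layout.arteriole_top_um),
                          (x, layout.act_depth_threshold_um),
                          layout.vertex_spacing_um),
                phenotype.tortuosity_amplitude, phenotype.tortuosity_wavelength,
                rng.uniform(0, 2 * np.pi)),
            diameter=layout.arteriole_diameter_um * dil,
            mean_speed=layout.arteriole_speed_mm_s * phenotype.speed_factor_arteriole,
            bubble_rate=layout.arteriole_rate,
            activated=activated and "penetrating_arteriole" in layout.activated_classes,
        ))
        if len(trunks) < min(layout.n_act_branches, layout.n_arterioles):
            # ACT trunk continues the penetrating path below the depth split
            start = art.centerline[-1]
            trunk = add(VesselSegmentSpec(
                id=(next_id := next_id + 1) - 1,
                vessel_class="ACT",
                centerline=_perturb(
                    _polyline(start, (start[0], layout.act_bottom_um),
                              layout.vertex_spacing_um),
                    phenotype.tortuosity_amplitude, phenotype.tortuosity_wavelength,
                    rng.uniform(0, 2 * np.pi)),
                diameter=layout.act_diameter_um * dil,
                mean_speed=layout.act_speed_mm_s * phenotype.speed_factor_act,
                parent=art.id,
                bubble_rate=layout.act_rate,
                activated=activated and "ACT" in layout.activated_classes,
            ))
            trunk._root_arteriole = i  # type: ignore[attr-defined]
            trunks.append(trunk)

    n_oblique = layout.n_act_branches - len(trunks)
    for _ in range(max(0, n_oblique)):
        trunk = trunks[rng.integers(len(trunks))]
        k = rng.integers(len(trunk.centerline) // 3, 2 * len(trunk.centerline) // 3)
        start = trunk.centerline[k]
        direction = rng.choice([-1.0, 1.0])
        length = rng.uniform(200, 350)
        end = start + np.array([direction * length * 0.8, length * 0.6])
        end[0] = np.clip(end[0], margin, layout.field_width_um - margin)
        root = getattr(trunk, "_root_arteriole", -1)
        add(VesselSegmentSpec(
            id=(next_id := next_id + 1) - 1,
            vessel_class="ACT",
            centerline=_polyline(start, end, layout.vertex_spacing_um),
            diameter=layout.act_diameter_um * dil,
            mean_speed=layout.act_speed_mm_s * phenotype.speed_factor_act,
            parent=trunk.id,
            bubble_rate=layout.act_rate,
            activated=(root in layout.activated_arterioles
                       and "ACT" in layout.activated_classes),
        ))

    for x in ven_x:
        # flow order: deep entry, shallow exit (ascending flow, v_z < 0)
        add(VesselSegmentSpec(
            id=(next_id := next_id + 1) - 1,
            vessel_class="venule",
            centerline=_polyline((x, layout.act_bottom_um),
                                 (x, layout.arteriole_top_um + 40.0),
                                 layout.vertex_spacing_um),
            diameter=layout.venule_diameter_um,
            mean_speed=layout.venule_speed_mm_s,
            bubble_rate=layout.venule_rate,
        ))

    _validate(segments, layout)
    return segments


def _validate(segments: list[VesselSegmentSpec], layout: TreeLayout) -> None:
    offenders = []
    for seg in segments:
        r = seg.diameter / 2
        c = seg.centerline
        if (c[:, 0].min() < r or c[:, 0].max() > layout.field_width_um - r
                or c[:, 1].min() < 0 or c[:, 1].max() > layout.field_depth_um - r):
            offenders.append(seg.id)
        if seg.vessel_class == "penetrating_arteriole" and seg.mean_vz_sign() <= 0:
            raise ValueError(f"arteriole {seg.id} does not flow downward")
        if seg.vessel_class == "venule" and seg.mean_vz_sign() >= 0:
            raise ValueError(f"venule {seg.id} does not flow upward")
        if seg.vessel_class == "ACT" and c[:, 1].min() < layout.act_depth_threshold_um - 1e-6:
            raise ValueError(
                f"ACT segment {seg.id} rises above the "
                f"{layout.act_depth_threshold_um} µm depth threshold")
    if offenders:
        raise ValueError(f"segments outside the field of view: {offenders}")
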