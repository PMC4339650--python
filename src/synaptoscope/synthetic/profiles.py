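"""Culture profiles: the parameter sets the synthetic field generator draws from.

A :class:`CultureProfile` describes one (cell type, DIV) condition of a dissociated
neuronal culture as seen by a high-content imager: how many neurons land in a
field of view, how large their somata are, how much dendrite they have grown,
and how densely excitatory (vGLUT1) and inhibitory (vGAT) presynaptic puncta
decorate dendrites and cell bodies.

The built-in presets encode the qualitative ontogeny of hippocampal and
cortical cultures over 7-28 days in vitro (DIV): puncta densities rise with
culture age, hippocampal somata become dominated by inhibitory (vGAT) puncta
from DIV 14 onward while their dendrites stay vGLUT1-dominated, and cortical
neurons keep an excitatory majority in both compartments.  Absolute counts are
synthetic: they are chosen to be realistic for 20x imaging at 0.5 um/pixel,
not to match any particular culture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

CELL_TYPES = ("hippocampal", "cortical")
DEFAULT_DIVS = (7, 14, 21, 28)


@dataclass(frozen=True)
class CultureProfile:
    """Expected composition of one imaging field for a culture condition.

    Parameters
    ----------
    cell_type : {"hippocampal", "cortical"}
    div : int
        Days in vitro (culture age).
    neurons_per_field : int
        Number of neurons placed per field (deterministic; each field of a
        condition receives exactly this many somata).
    soma_radius_um : tuple of float
        Mean and s.d. of the soma radius in micrometres.
    nucleus_radius_um : float
        Nucleus radius in micrometres (rendered as a Gaussian blob).
    dendrites_per_neuron : tuple of int
        Inclusive (min, max) number of primary dendrites per neuron.
    dendrite_length_um : float
        Mean *total* dendrite length per neuron in micrometres.
    vglut_density_per_um, vgat_density_per_um : float
        Expected dendritic puncta per micrometre of dendrite, per channel.
    vglut_soma_count, vgat_soma_count : float
        Expected puncta per neuronal cell body, per channel.
    axonal_background_rate : float
        Expected distractor puncta per field lying on neither a soma nor a
        dendrite (emulating terminals on MAP2-negative processes).
    axon_streaks_per_field : float
        Expected number of continuous low-intensity axon-like streaks rendered
        in the vGLUT1 plane only (they carry no ground-truth puncta).
    """

    cell_type: str
    div: int
    neurons_per_field: int = 5
    soma_radius_um: tuple[float, float] = (7.5, 0.8)
    nucleus_radius_um: float = 3.0
    dendrites_per_neuron: tuple[int, int] = (2, 4)
    dendrite_length_um: float = 250.0
    vglut_density_per_um: float = 0.12
    vgat_density_per_um: float = 0.04
    vglut_soma_count: float = 5.0
    vgat_soma_count: float = 12.0
    axonal_background_rate: float = 4.0
    axon_streaks_per_field: float = 2.0

    def validate(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(
                f"unknown cell_type {self.cell_type!r}; expected one of {CELL_TYPES}"
            )
        if self.div <= 0:
            raise ValueError("div must be a positive number of days in vitro")
        if self.neurons_per_field < 0:
            raise ValueError("neurons_per_field must be >= 0")
        for name in (
            "vglut_density_per_um",
            "vgat_density_per_um",
            "vglut_soma_count",
            "vgat_soma_count",
            "axonal_background_rate",
            "axon_streaks_per_field",
            "dendrite_length_um",
            "nucleus_radius_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.soma_radius_um[0] <= 0 or self.soma_radius_um[1] < 0:
            raise ValueError("soma_radius_um must be (mean > 0, sd >= 0)")
        lo, hi = self.dendrites_per_neuron
        if not (0 <= lo <= hi):
            raise ValueError("dendrites_per_neuron must be an ordered nonneg range")

    def with_(self, **kwargs) -> "CultureProfile":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# Preset ontogeny: (dendrite_length_um, vglut/um, vgat/um, vglut/soma, vgat/soma)
# Densities are non-decreasing in DIV; hippocampal somata flip to vGAT-dominated
# at DIV >= 14, cortical somata stay vGLUT1-dominated throughout.
_HIPPOCAMPAL = {
    7: (120.0, 0.06, 0.020, 4.0, 3.0),
    14: (250.0, 0.12, 0.040, 5.0, 12.0),
    21: (380.0, 0.18, 0.060, 6.0, 16.0),
    28: (400.0, 0.24, 0.080, 7.0, 20.0),
}
_CORTICAL = {
    7: (90.0, 0.03, 0.012, 4.0, 2.0),
    14: (130.0, 0.06, 0.030, 5.0, 2.5),
    21: (220.0, 0.12, 0.050, 6.0, 3.0),
    28: (300.0, 0.20, 0.080, 8.0, 4.0),
}


def preset_profile(cell_type: str, div: int) -> CultureProfile:
    """Return the built-in profile for a (cell type, DIV) condition."""
    if cell_type == "hippocampal":
        table, n_field, soma = _HIPPOCAMPAL, 5, (7.5, 0.8)
    elif cell_type == "cortical":
        # cortical cultures are plated denser: more, slightly smaller neurons
        table, n_field, soma = _CORTICAL, 8, (7.0, 0.8)
    else:
        raise ValueError(
            f"unknown cell_type {cell_type!r}; expected one of {CELL_TYPES}"
        )
    if div not in table:
        raise ValueError(f"no preset for div={div}; presets cover {sorted(table)}")
    length, vglut_d, vgat_d, vglut_s, vgat_s = table[div]
    prof = CultureProfile(
        cell_type=cell_type,
        div=div,
        neurons_per_field=n_field,
        soma_radius_um=soma,
        dendrite_length_um=length,
        vglut_density_per_um=vglut_d,
        vgat_density_per_um=vgat_d,
        vglut_soma_count=vglut_s,
        vgat_soma_count=vgat_s,
    )
    prof.validate()
    return prof
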