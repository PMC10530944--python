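import numpy as np
import pytest

from eigenstep import SynthSpec, generate_dataset


def make_class_instance(
    rng: np.random.Generator,
    n: int = 60,
    p: int = 6,
    n_classes: int = 3,
    informative: tuple[int, ...] = (),
    effect: float = 3.0,
):
    """Random tabular instance: standard-normal features, optional planted signal.

    Planted columns get a class-dependent mean offset of ``effect`` standard
    deviations, so they carry all the class information.
    """
    y = rng.integers(0, n_classes, size=n)
    # guarantee every class appears
    y[:n_classes] = np.arange(n_classes)
    x = rng.standard_normal((n, p))
    offsets = rng.standard_normal((n_classes, len(informative)))
    offsets = effect * offsets / np.maximum(np.abs(offsets).max(), 1e-9)
    for k, col in enumerate(informative):
        x[:, col] += offsets[y, k]
    return x, y


@pytest.fixture(scope="session")
def small_phantom():
    """120-image 4-class phantom with clear class signal, 24x24 pixels."""
    spec = SynthSpec(
        image_height=24,
        image_width=24,
        n_per_class=(30, 30, 30, 30),
        effect_size=1.0,
        noise_sd=0.05,
        n_signal_modes=4,
        seed=42,
    )
    return spec, generate_dataset(spec)
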