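import numpy as np
import pytest

from spherotype import synthgen


@pytest.fixture(scope="session")
def disk_mask():
    return synthgen.render_spheroid(30)


@pytest.fixture(scope="session")
def spiky_mask():
    return synthgen.render_spheroid(30, n_protrusions=6,
                                    protrusion_length=0.8,
                                    protrusion_width=0.15)


@pytest.fixture(scope="session")
def sharp_blurred_pair():
    """The same single-spheroid scene rendered sharp and defocused."""
    st = synthgen.SpheroidState(centroid=(64.0, 64.0), radius=20.0)
    sharp = synthgen.render_frame([st], np.random.default_rng(5), 128,
                                  pixel_noise_sd=0.02, blur_sigma=0.0)
    blurred = synthgen.render_frame([st], np.random.default_rng(5), 128,
                                    pixel_noise_sd=0.02, blur_sigma=4.0)
    return sharp, blurred


@pytest.fixture(scope="session")
def small_experiment():
    """One condition, one replicate, rendered: shared by seg/track tests."""
    cfg = synthgen.SynthConfig(
        conditions=[synthgen.ConditionSpec(
            name="mix", p_hyper=0.4, p_outfocus=0.0, drift_sd=1.5)],
        image_size=256, n_frames=15, n_experiments=1,
        wells_per_condition=2, spheroids_per_well=4, seed=11)
    return synthgen.simulate_experiment(cfg, render=True)
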