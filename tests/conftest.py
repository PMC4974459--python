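import pytest

from convoyquant import ConvoyParams, GeneGeometry


@pytest.fixture
def geom():
    """Default MS2x128 reporter geometry."""
    return GeneGeometry()


@pytest.fixture
def simple_geom():
    """Geometry with no leader, used by hand-computable examples."""
    return GeneGeometry(l_pre=0.0, l_ms2=1000.0, l_post=1000.0)


@pytest.fixture
def hiv_params():
    """Convoy parameters at the fitted means of the Tat-activated reporter."""
    return ConvoyParams(n_pol=19, t_space=4.1, v_el=4.1, t_proc=103.0)


def event_list_intensity(t, n_pol, t_space, v_el_kb_min, t_proc, geom, t0=0.0):
    """Independent per-polymerase oracle: enumerate entry/exit/release times
    for each polymerase and sum the contributions at time t."""
    v = v_el_kb_min * 1000.0 / 60.0  # nt/s
    total = 0.0
    for i in range(n_pol):
        ti = t0 + i * t_space
        t_enter = ti + geom.l_pre / v
        t_exit = ti + (geom.l_pre + geom.l_ms2) / v
        t_release = ti + (geom.l_pre + geom.l_ms2 + geom.l_post) / v + t_proc
        if t >= t_release or t < t_enter:
            contrib = 0.0
        elif t < t_exit:
            contrib = (t - t_enter) / (t_exit - t_enter)
        else:
            contrib = 1.0
        total += contrib
    return total
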