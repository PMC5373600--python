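import pytest

from breastdwi import (
    Distribution,
    InternalPattern,
    LesionRecord,
    LesionType,
    Margin,
    Pathology,
    Shape,
)


def make_mass(shape=Shape.OVAL, margin=Margin.CIRCUMSCRIBED,
              pattern=InternalPattern.HOMOGENEOUS, *, adc=1.1, size=1.2,
              birads=4, pathology=Pathology.BENIGN, lesion_id="m"):
    return LesionRecord(
        lesion_id=lesion_id, pathology=pathology, dwi_visible=True,
        lesion_type=LesionType.MASS, shape=shape, margin=margin,
        internal_pattern=pattern, adc=adc, size_cm=size, birads=birads)


def make_nonmass(distribution=Distribution.FOCAL,
                 pattern=InternalPattern.HOMOGENEOUS, *, adc=1.1, size=1.2,
                 birads=4, pathology=Pathology.BENIGN, lesion_id="n"):
    return LesionRecord(
        lesion_id=lesion_id, pathology=pathology, dwi_visible=True,
        lesion_type=LesionType.NONMASS, distribution=distribution,
        internal_pattern=pattern, adc=adc, size_cm=size, birads=birads)


def make_invisible(*, size=0.5, birads=3, pathology=Pathology.BENIGN,
                   lesion_id="i"):
    return LesionRecord(lesion_id=lesion_id, pathology=pathology,
                        dwi_visible=False, size_cm=size, birads=birads)


@pytest.fixture(scope="session")
def small_cohort():
    """One invisible benign lesion, one mass, one non-mass."""
    return [
        make_invisible(lesion_id="L1"),
        make_mass(lesion_id="L2", pathology=Pathology.MALIGNANT,
                  shape=Shape.IRREGULAR, margin=Margin.SPICULATED,
                  pattern=InternalPattern.RIM, adc=0.72, size=2.3, birads=5),
        make_nonmass(lesion_id="L3", distribution=Distribution.FOCAL,
                     pattern=InternalPattern.HETEROGENEOUS, adc=1.34,
                     size=0.9, birads=3),
    ]
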