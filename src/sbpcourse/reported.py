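"""Published reference-course coefficients and cohort counts.

These constants are worked-example *inputs*: fixed-effect estimates of the
reference SBP courses and headline counts from the source study's cohort.
They are used by the acceptance report and the worked-example tests, never
by the estimation code itself.
"""

from __future__ import annotations

import numpy as np

from .course_model import CourseSpec, ReferenceCourse

__all__ = [
    "REFERENCE_FIXED_EFFECTS",
    "COHORT_COUNTS",
    "published_course",
]

#: Fixed effects (level, trend, curvature, twist as applicable) of the
#: published reference courses, keyed by (outcome name, polynomial degree).
REFERENCE_FIXED_EFFECTS: dict[tuple[str, int], tuple[float, ...]] = {
    ("functional_independence", 1): (129.78, -0.28378),
    ("functional_independence", 2): (132.50, -1.2406, 0.04379),
    ("functional_independence", 3): (133.54, -1.9443, 0.12573, -0.00240),
    ("alive", 1): (131.02, -0.23423),
    ("alive", 2): (133.34, -1.0488, 0.03721),
    ("alive", 3): (134.06, -1.5385, 0.09416, -0.00166),
    ("no_sich", 1): (131.99, -0.21927),
    ("no_sich", 2): (134.06, -0.94195, 0.03302),
    ("no_sich", 3): (134.57, -1.2899, 0.07348, -0.00118),
    ("no_ich", 1): (132.22, -0.22255),
    ("no_ich", 2): (134.27, -0.93689, 0.03259),
    ("no_ich", 3): (134.93, -1.3832, 0.08448, -0.00151),
}

#: Headline cohort counts: registered patients, favourable counts per
#: outcome, and the number excluded by the >= 10-measurement filter.
COHORT_COUNTS = {
    "registered": 374,
    "functional_independence": 169,
    "alive": 292,
    "no_sich": 354,
    "no_ich": 321,
    "excluded_lt10_measurements": 58,
}


def published_course(outcome_name: str, degree: int) -> ReferenceCourse:
    """A ReferenceCourse carrying the published fixed effects.

    The published G matrices and residual variances are not tabulated here,
    so placeholder values (identity G, unit residual variance) are used;
    the course is therefore only valid for fixed-effects evaluation.
    """
    alpha = REFERENCE_FIXED_EFFECTS[(outcome_name, degree)]
    return ReferenceCourse(
        spec=CourseSpec(degree=degree, outcome_name=outcome_name),
        alpha=np.asarray(alpha),
        G=np.eye(degree + 1),
        sigma2=1.0,
    )
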