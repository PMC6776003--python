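"""Bundled reference data.

``EIGHT_PARTICIPANT_SUMMARY`` is the published per-participant residency
summary of an eight-adult longitudinal stool-sampling cohort (the worked
example this package's summary table reproduces): for each participant the
number of samples, the sampled span in days, the number of OTUs observed,
and resident / always-resident OTU counts under the min / ave / max
residence-time estimators. Transient counts are the observed-OTU
complement of the resident counts.
"""

from __future__ import annotations

from .cohort import SubjectSummary

# subject, samples, days, OTUs, (min res, min always), (ave res, ave always),
# (max res, max always)
_ROWS = [
    ("1", 76, 722, 220, (170, 63), (196, 76), (215, 92)),
    ("2", 43, 342, 244, (181, 90), (206, 99), (223, 105)),
    ("3", 24, 425, 189, (151, 65), (179, 80), (185, 95)),
    ("4", 29, 480, 186, (145, 51), (163, 57), (178, 97)),
    ("5", 38, 412, 179, (137, 62), (158, 77), (177, 92)),
    ("6", 48, 412, 181, (111, 56), (125, 63), (145, 82)),
    ("7", 42, 399, 242, (196, 80), (213, 90), (231, 107)),
    ("8", 24, 245, 181, (142, 83), (158, 94), (171, 106)),
]


def eight_participant_summary() -> list[SubjectSummary]:
    """The published per-participant rows as SubjectSummary objects."""
    out = []
    for subject, n_samples, days, n_otus, mn, av, mx in _ROWS:
        tallies = {
            "min": (mn[0], n_otus - mn[0], mn[1]),
            "ave": (av[0], n_otus - av[0], av[1]),
            "max": (mx[0], n_otus - mx[0], mx[1]),
        }
        out.append(SubjectSummary(subject, n_samples, days, n_otus, tallies))
    return out
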