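"""Shared tiny-dataset builder for survey tests."""

from dogpop.synthetic_data import CallRecord, DogRecord, SurveyDataset


def make_dataset(area_calls, flags=None):
    """Build a SurveyDataset from {area: [(order, valid, n_dogs), ...]}.

    ``flags[(area, order, j)]`` sets the (vet, insured, kc, pets) tuple of
    the j-th dog of that household; unset dogs carry all-False flags.
    """
    calls, dogs = [], []
    flags = flags or {}
    for area, rows in area_calls.items():
        for order, valid, n_dogs in rows:
            call = CallRecord(area, order, valid, n_dogs)
            calls.append(call)
            for j in range(n_dogs):
                f = flags.get((area, order, j), (False, False, False, False))
                dogs.append(DogRecord(call.household_id, area, *f))
    return SurveyDataset(list(area_calls), calls, dogs)
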