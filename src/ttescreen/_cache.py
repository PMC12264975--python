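"""Per-DataFrame memoization keyed by object identity.

Screens recompute identical derived tables (categorized fills, fixed-width
code arrays) for every trial of the same snapshot; storing them in
``DataFrame.attrs`` is not an option because pandas deep-copies attrs on
every copy.  Entries are evicted when the source frame is garbage
collected.
"""

from __future__ import annotations

import weakref

_store: dict[int, dict] = {}


def memoize_by_id(df, key, compute):
    ident = id(df)
    bucket = _store.get(ident)
    if bucket is None:
        bucket = {}
        _store[ident] = bucket
        try:
            weakref.finalize(df, _store.pop, ident, None)
        except TypeError:  # not weakref-able: skip eviction hook
            pass
    if key not in bucket:
        bucket[key] = compute()
    return bucket[key]
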