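"""Sorting primitives that count inversions.

The number of "swaps" reported by both sorts equals the number of
inversions in the input: pairs (i, j) with i < j and values[i] > values[j].
Ties never count as inversions. This is the quantity Knight's algorithm
needs — after sorting observations by x, the inversion count of the
carried-along y sequence equals the number of discordant pairs.

Counters are plain Python ints, so pair counts up to n(n-1)/2 never
overflow regardless of n.
"""

from __future__ import annotations

# Below this length the recursive sort falls back to insertion sort,
# which is faster on tiny arrays.
INSERTION_SORT_THRESHOLD = 10


def insertion_sort_count(values) -> tuple[list, int]:
    """Sort ``values`` ascending, counting inversions.

    Returns ``(sorted_list, swaps)`` where ``swaps`` is the number of
    element shifts performed, which equals the inversion count of the
    input (ties excluded). The input is not modified.
    """
    arr = list(values)
    swaps = 0
    for i in range(1, len(arr)):
        key = arr[i]
        j = i - 1
        while j >= 0 and arr[j] > key:
            arr[j + 1] = arr[j]
            swaps += 1
            j -= 1
        arr[j + 1] = key
    return arr, swaps


def merge_sort_count(values, threshold: int = INSERTION_SORT_THRESHOLD) -> tuple[list, int]:
    """Sort ``values`` ascending via merge sort, counting inversions.

    Arrays shorter than ``threshold`` are handled by insertion sort.
    The swap count accumulates across the recursive splits and the
    merges, and equals the total inversion count of the input.
    """
    arr = list(values)
    swaps = _merge_sort_inplace(arr, threshold)
    return arr, swaps


def _merge_sort_inplace(arr: list, threshold: int) -> int:
    n = len(arr)
    if n < threshold:
        sorted_arr, swaps = insertion_sort_count(arr)
        arr[:] = sorted_arr
        return swaps
    mid = n // 2
    left = arr[:mid]
    right = arr[mid:]
    swaps = _merge_sort_inplace(left, threshold)
    swaps += _merge_sort_inplace(right, threshold)
    swaps += _merge(left, right, arr)
    return swaps


def _merge(left: list, right: list, out: list) -> int:
    """Merge two sorted lists into ``out``; return cross inversions.

    Taking an element from ``right`` while elements remain in ``left``
    means it inverts with every one of them. Equal elements are taken
    from ``left`` first, so ties contribute nothing.
    """
    swaps = 0
    i = j = k = 0
    nl, nr = len(left), len(right)
    while i < nl and j < nr:
        if right[j] < left[i]:
            out[k] = right[j]
            j += 1
            swaps += nl - i
        else:
            out[k] = left[i]
            i += 1
        k += 1
    while i < nl:
        out[k] = left[i]
        i += 1
        k += 1
    while j < nr:
        out[k] = right[j]
        j += 1
        k += 1
    return swaps


def count_tie_pairs(sorted_values) -> int:
    """Number of tied pairs in a nondecreasing sequence.

    For each run of L equal values the run contributes L(L-1)/2 pairs
    (equivalently tz(tz+1)/2 with tz = L-1 consecutive-equal
    transitions). Input must already be sorted; unsorted input is a
    contract violation.
    """
    total = 0
    run = 1
    it = iter(sorted_values)
    try:
        prev = next(it)
    except StopIteration:
        return 0
    for v in it:
        if v == prev:
            run += 1
        else:
            total += run * (run - 1) // 2
            run = 1
            prev = v
    total += run * (run - 1) // 2
    return total
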