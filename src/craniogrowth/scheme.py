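"""Landmark naming scheme for the basicranial-facial configuration.

The analysis uses 18 bony landmarks of the cranial base and face: 8 on the
midsagittal plane and 5 bilateral pairs.  Bilateral pairing is what makes the
object-symmetry (reflection/relabelling) decomposition well defined, so the
scheme carries both the names and the pairing structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Midline landmarks: anterior nasal spine, basion, dorsum sellae, nasion,
#: opisthion, posterior nasal spine, sella, tuberculum sellae.
MIDLINE_NAMES = ("Ans", "Ba", "Ds", "Na", "Op", "Pns", "S", "Ts")

#: Bilaterally paired landmarks: condylion, inferior / lateral / medial /
#: superior orbital margins.
PAIRED_NAMES = ("Cd", "Io", "Lo", "Mo", "So")


@dataclass(frozen=True)
class LandmarkScheme:
    """Names plus midline/pair structure of a landmark configuration.

    Attributes
    ----------
    names : tuple of str
        One label per landmark, length ``n_landmarks``.
    pairing : tuple of (int, int)
        Index pairs ``(left, right)`` for bilateral landmarks.
    midline : tuple of int
        Indices of midsagittal landmarks.
    """

    names: tuple[str, ...]
    pairing: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.names)
        paired = [i for pair in self.pairing for i in pair]
        if len(set(paired)) != len(paired):
            raise ValueError("pairing indices must be distinct")
        if set(paired) & set(self.midline):
            raise ValueError("a landmark cannot be both midline and paired")
        if len(self.midline) + len(paired) != n:
            raise ValueError("every landmark must be midline or in a pair")
        if any(not (0 <= i < n) for i in paired + list(self.midline)):
            raise ValueError("landmark index out of range")

    @property
    def n_landmarks(self) -> int:
        return len(self.names)

    def relabel_permutation(self) -> list[int]:
        """Permutation swapping left and right labels (midline fixed).

        Applying it twice is the identity (the pairing is involutive).
        """
        perm = list(range(self.n_landmarks))
        for left, right in self.pairing:
            perm[left], perm[right] = right, left
        return perm

    def index(self, name: str) -> int:
        return self.names.index(name)


def default_scheme() -> LandmarkScheme:
    """The 18-landmark basicranial-facial scheme (8 midline + 5 pairs).

    Order: the 8 midline landmarks first (alphabetical), then left/right
    columns for each of the 5 pairs.
    """
    names = list(MIDLINE_NAMES)
    pairing = []
    for nm in PAIRED_NAMES:
        left = len(names)
        names += [nm + "_L", nm + "_R"]
        pairing.append((left, left + 1))
    return LandmarkScheme(
        names=tuple(names),
        pairing=tuple(pairing),
        midline=tuple(range(len(MIDLINE_NAMES))),
    )
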