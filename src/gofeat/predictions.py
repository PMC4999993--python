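"""Prediction sets: (protein, GO term, score) triples with 3-decimal scores."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import ParseError, ValidationError


def round3(score: float) -> float:
    """Scores are reported rounded to three decimals throughout."""
    return round(float(score), 3)


@dataclass
class PredictionSet:
    """Per-protein GO term confidence scores in [0, 1]."""

    scores: dict[str, dict[str, float]] = field(default_factory=dict)

    def add(self, protein: str, term: str, score: float,
            keep_max: bool = True) -> None:
        score = round3(score)
        if not 0.0 <= score <= 1.0:
            raise ValidationError(f"score {score} outside [0, 1]")
        slot = self.scores.setdefault(protein, {})
        if keep_max and term in slot:
            slot[term] = max(slot[term], score)
        else:
            slot[term] = score

    def for_protein(self, protein: str) -> dict[str, float]:
        return dict(self.scores.get(protein, {}))

    @property
    def proteins(self) -> set[str]:
        return set(self.scores)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for d in self.scores.values():
            out |= set(d)
        return out

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        for prot in sorted(self.scores):
            for term in sorted(self.scores[prot]):
                yield prot, term, self.scores[prot][term]

    def __len__(self) -> int:
        return sum(len(d) for d in self.scores.values())

    def to_tsv(self) -> str:
        lines = [f"{p}\t{t}\t{s:.3f}" for p, t, s in self]
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_tsv(cls, text: str) -> "PredictionSet":
        ps = cls()
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"prediction line {lineno}: need 3 columns")
            ps.add(parts[0], parts[1], float(parts[2]))
        return ps

    @classmethod
    def from_triples(cls, triples: Iterable[tuple[str, str, float]]
                     ) -> "PredictionSet":
        ps = cls()
        for p, t, s in triples:
            ps.add(p, t, s)
        return ps
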