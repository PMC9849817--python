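"""Dataset model: triplet records, manifest I/O, splits, answer vocabulary,
and the synthetic corpus generator.

A corpus is a list of (image, question, answers) triplet records.  Every image
carries exactly two questions; every train/val question carries exactly three
answer annotations; test questions carry none.  Splits are assigned by fixing
the validation and test sizes at absolute counts and giving the training split
the remainder (so 8,450 images with val=test=850 yields 6,750 train images).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .errors import InvalidInputError, ManifestParseError

QUESTION_TYPES = ("yesno", "number", "whatwhere", "other")
SPLITS = ("train", "val", "test")

# Palette used by the synthetic generator; names double as answer strings.
LESION_COLORS = {
    "brown": (139, 69, 19),
    "black": (20, 20, 20),
    "yellow": (218, 185, 50),
}
SPECIES = ("litchi", "longan", "grape", "citrus")
QUADRANTS = ("top left", "top right", "bottom left", "bottom right")


@dataclass
class VQARecord:
    """One (image, question, answer-annotations) triplet entry."""

    image_id: str
    image_path: str
    question_id: str
    question: str
    question_type: str
    answers: list[str] = field(default_factory=list)
    candidates: list[str] | None = None
    split: str = "train"

    def validate(self) -> "VQARecord":
        if self.question_type not in QUESTION_TYPES:
            raise InvalidInputError(
                f"unknown question_type {self.question_type!r}; "
                f"expected one of {QUESTION_TYPES}")
        if self.split not in SPLITS:
            raise InvalidInputError(f"unknown split {self.split!r}")
        if self.split == "test" and self.answers:
            raise InvalidInputError("test records must carry no answer annotations")
        if self.split != "test" and len(self.answers) != 3:
            raise InvalidInputError(
                f"{self.split} records must carry exactly 3 annotations, "
                f"got {len(self.answers)}")
        if self.candidates is not None and len(self.candidates) != 4:
            raise InvalidInputError("candidates must contain exactly 4 answers")
        return self

    @property
    def label(self) -> str:
        """Training label: majority of the 3 annotations, first annotator
        breaking ties."""
        if not self.answers:
            raise InvalidInputError("record has no annotations (test split?)")
        best, best_count = self.answers[0], 0
        for a in self.answers:
            c = self.answers.count(a)
            if c > best_count:
                best, best_count = a, c
        return best


@dataclass
class SplitSpec:
    """Absolute val/test sizes; train takes the remainder."""

    val_images: int
    test_images: int
    seed: int = 0

    def validate(self, total: int) -> "SplitSpec":
        if self.val_images < 0 or self.test_images < 0:
            raise InvalidInputError("split counts must be nonnegative")
        if self.val_images + self.test_images > total:
            raise InvalidInputError(
                f"val+test ({self.val_images + self.test_images}) exceeds "
                f"total images ({total})")
        return self


@dataclass
class SynthConfig:
    n_images: int = 20
    image_size: int = 128
    lesion_count_range: tuple[int, int] = (0, 5)
    leaf_color: tuple[int, int, int] = (34, 139, 34)
    type_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def validate(self) -> "SynthConfig":
        if self.n_images < 1:
            raise InvalidInputError("n_images must be >= 1")
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise InvalidInputError("type_mix must sum to 1")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise InvalidInputError("invalid lesion_count_range")
        return self


@dataclass
class Manifest:
    records: list[VQARecord]
    answer_vocab: list[str] = field(default_factory=list)

    @property
    def split_counts(self) -> dict[str, tuple[int, int, int]]:
        counts = {}
        for split in SPLITS:
            recs = [r for r in self.records if r.split == split]
            images = len({r.image_id for r in recs})
            counts[split] = (images, len(recs), sum(len(r.answers) for r in recs))
        return counts

    def subset(self, split: str) -> list[VQARecord]:
        return [r for r in self.records if r.split == split]


# ---------------------------------------------------------------------------
# Split construction
# ---------------------------------------------------------------------------

def assign_splits(image_ids: list[str], spec: SplitSpec) -> dict[str, str]:
    """Deterministically shuffle image ids and map each to a split."""
    if not image_ids:
        raise InvalidInputError("image id list is empty")
    if len(set(image_ids)) != len(image_ids):
        raise InvalidInputError("image ids must be unique")
    spec.validate(len(image_ids))
    order = np.random.default_rng(spec.seed).permutation(len(image_ids))
    shuffled = [image_ids[i] for i in order]
    mapping = {}
    for i, img in enumerate(shuffled):
        if i < spec.val_images:
            mapping[img] = "val"
        elif i < spec.val_images + spec.test_images:
            mapping[img] = "test"
        else:
            mapping[img] = "train"
    return mapping


def build_manifest(image_ids: list[str], spec: SplitSpec,
                   records: list[VQARecord] | None = None,
                   questions_per_image: int = 2,
                   annotations_per_question: int = 3) -> Manifest:
    """Partition images into splits and produce the manifest.

    When `records` is given, their split fields are rewritten according to the
    partition (and test answers stripped).  Otherwise placeholder question
    records are synthesized: `questions_per_image` per image, each carrying
    `annotations_per_question` annotations on non-test splits.
    """
    mapping = assign_splits(image_ids, spec)
    if records is None:
        records = []
        for img in image_ids:
            for j in range(questions_per_image):
                records.append(VQARecord(
                    image_id=img, image_path=f"{img}.png",
                    question_id=f"{img}_q{j}",
                    question="is the fruit tree diseased",
                    question_type="yesno",
                    answers=["yes"] * annotations_per_question,
                    split="train"))
    out = []
    for rec in records:
        rec = dataclasses.replace(rec, split=mapping[rec.image_id])
        if rec.split == "test":
            rec.answers = []
        out.append(rec)
    manifest = Manifest(records=out)
    try:
        manifest.answer_vocab = build_answer_vocabulary(manifest)
    except InvalidInputError:
        manifest.answer_vocab = []
    return manifest


def build_answer_vocabulary(manifest: Manifest) -> list[str]:
    """Unique answers from train then val annotations, first-occurrence order."""
    vocab: list[str] = []
    seen: set[str] = set()
    for split in ("train", "val"):
        for rec in manifest.subset(split):
            for a in rec.answers:
                if a not in seen:
                    seen.add(a)
                    vocab.append(a)
    if not vocab:
        raise InvalidInputError("manifest has no annotated answers")
    return vocab


# ---------------------------------------------------------------------------
# Manifest I/O (JSON lines, one record per line, UTF-8)
# ---------------------------------------------------------------------------

_FIELDS = ("image_id", "image_path", "question_id", "question",
           "question_type", "answers", "candidates", "split")


def write_manifest(path: str | os.PathLike, manifest: Manifest) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in manifest.records:
            row = {f: getattr(rec, f) for f in _FIELDS}
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")


def read_manifest(path: str | os.PathLike) -> Manifest:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                row = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ManifestParseError(f"invalid JSON ({exc.msg})", lineno) from exc
            unknown = set(row) - set(_FIELDS)
            if unknown:
                raise ManifestParseError(f"unknown fields {sorted(unknown)}", lineno)
            try:
                rec = VQARecord(**{f: row.get(f) for f in _FIELDS
                                   if row.get(f) is not None or f == "candidates"})
                rec.answers = list(row.get("answers") or [])
                rec.validate()
            except (TypeError, InvalidInputError) as exc:
                raise ManifestParseError(str(exc), lineno) from exc
            records.append(rec)
    manifest = Manifest(records=records)
    if records:
        try:
            manifest.answer_vocab = build_answer_vocabulary(manifest)
        except InvalidInputError:
            manifest.answer_vocab = []
    return manifest


# ---------------------------------------------------------------------------
# Synthetic corpus generation
# ---------------------------------------------------------------------------

def _lesion_quadrant(centers: list[tuple[float, float]], size: int) -> str:
    """Quadrant holding the most lesion centers (ties: earliest in QUADRANTS)."""
    votes = dict.fromkeys(QUADRANTS, 0)
    for (x, y) in centers:
        row = "top" if y < size / 2 else "bottom"
        col = "left" if x < size / 2 else "right"
        votes[f"{row} {col}"] += 1
    return max(QUADRANTS, key=lambda q: (votes[q], -QUADRANTS.index(q)))


def derive_answer(question_type: str, params: dict, variant: int = 0) -> tuple[str, str]:
    """Ground-truth (question, answer) for a question type from image
    generation parameters.  `variant` selects among templates of a type."""
    k = params["n_lesions"]
    if question_type == "yesno":
        return "is the fruit tree diseased", ("yes" if k > 0 else "no")
    if question_type == "number":
        return "how many lesions are on the leaf", str(k)
    if question_type == "whatwhere":
        if variant % 2 == 0:
            return ("what color are the lesions",
                    params["lesion_color"] if k > 0 else "none")
        return ("where are the lesions",
                params["quadrant"] if k > 0 else "nowhere")
    return "what plant is in the image", params["species"]


def _distractor(question_type: str, answer: str, params: dict,
                rng: np.random.Generator) -> str:
    """One plausible wrong annotation (the third annotator's dissent)."""
    if question_type == "yesno":
        return "no" if answer == "yes" else "yes"
    if question_type == "number":
        k = int(answer)
        return str(k + 1 if k == 0 or rng.random() < 0.5 else k - 1)
    if question_type == "whatwhere":
        pool = [c for c in LESION_COLORS if c != answer] + \
               [q for q in QUADRANTS if q != answer]
        return pool[int(rng.integers(len(pool)))]
    pool = [s for s in SPECIES if s != answer]
    return pool[int(rng.integers(len(pool)))]


def _candidates(question_type: str, answer: str, params: dict,
                rng: np.random.Generator) -> list[str]:
    """Four multiple-choice candidates always containing the ground truth."""
    cands = {answer}
    while len(cands) < 4:
        if question_type == "number":
            cands.add(str(int(rng.integers(0, 9))))
        elif question_type == "yesno":
            cands.update(("yes", "no"))
            cands.add(str(int(rng.integers(0, 9))))
        else:
            pool = list(LESION_COLORS) + list(QUADRANTS) + list(SPECIES)
            cands.add(pool[int(rng.integers(len(pool)))])
    out = sorted(cands)[:4]
    if answer not in out:
        out[0] = answer
    order = rng.permutation(4)
    return [out[i] for i in order]


BACKGROUND_COLOR = (4, 4, 4)


def _draw_image(size: int, leaf_color, lesion_rgb, centers, radii) -> Image.Image:
    """Dark field, bright leaf disc, lesions on the leaf — so the foreground
    extractor keeps the leaf (and its lesions) rather than cropping them out."""
    img = Image.new("RGB", (size, size), BACKGROUND_COLOR)
    draw = ImageDraw.Draw(img)
    m = size * 0.06
    draw.ellipse([m, m, size - m, size - m], fill=leaf_color)
    for (x, y), (rx, ry) in zip(centers, radii):
        draw.ellipse([x - rx, y - ry, x + rx, y + ry], fill=lesion_rgb)
    return img


def generate_synthetic_corpus(cfg: SynthConfig, out_dir: str | os.PathLike,
                              split: SplitSpec | None = None
                              ) -> tuple[Manifest, dict]:
    """Write `cfg.n_images` lesion-bearing PNGs plus a manifest.

    Per image: leaf-colored square, k elliptical lesions (k uniform over
    `lesion_count_range`), exactly 2 questions drawn from `type_mix`, 3
    annotations per non-test question (ground truth twice + one distractor)
    and 4 multiple-choice candidates.  Returns the manifest and the per-image
    generation parameters (also written to `generation.json`) from which every
    stored answer can be re-derived.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    lo, hi = cfg.lesion_count_range
    records: list[VQARecord] = []
    gen_params: dict[str, dict] = {}
    for i in range(cfg.n_images):
        image_id = f"img{i:05d}"
        k = int(rng.integers(lo, hi + 1))
        color_name = list(LESION_COLORS)[int(rng.integers(len(LESION_COLORS)))]
        species = SPECIES[int(rng.integers(len(SPECIES)))]
        # lesion centers inside the leaf disc, radii visible at coarse grids
        centers = []
        for _ in range(k):
            ang = rng.uniform(0.0, 2 * np.pi)
            rad = np.sqrt(rng.uniform(0.0, 1.0)) * size * 0.27
            centers.append((float(size / 2 + rad * np.cos(ang)),
                            float(size / 2 + rad * np.sin(ang))))
        radii = [(float(rng.uniform(size / 14, size / 9)),
                  float(rng.uniform(size / 14, size / 9))) for _ in range(k)]
        params = {
            "n_lesions": k,
            "lesion_color": color_name,
            "species": species,
            "quadrant": _lesion_quadrant(centers, size) if k else "nowhere",
            "centers": centers,
            "radii": radii,
        }
        gen_params[image_id] = params
        # paths are stored relative to the corpus directory so manifests are
        # byte-identical across locations; loaders resolve via image_root
        path = f"{image_id}.png"
        _draw_image(size, cfg.leaf_color, LESION_COLORS[color_name],
                    centers, radii).save(out_dir / path)
        for j in range(2):
            qtype = QUESTION_TYPES[int(rng.choice(4, p=np.asarray(cfg.type_mix)))]
            question, answer = derive_answer(qtype, params, variant=j)
            annotations = [answer, answer,
                           _distractor(qtype, answer, params, rng)]
            records.append(VQARecord(
                image_id=image_id, image_path=str(path),
                question_id=f"{image_id}_q{j}", question=question,
                question_type=qtype, answers=annotations,
                candidates=_candidates(qtype, answer, params, rng),
                split="train"))
    if split is not None:
        manifest = build_manifest([f"img{i:05d}" for i in range(cfg.n_images)],
                                  split, records=records)
    else:
        manifest = Manifest(records=records)
        manifest.answer_vocab = build_answer_vocabulary(manifest)
    with open(out_dir / "generation.json", "w", encoding="utf-8") as fh:
        json.dump(gen_params, fh, indent=1)
    write_manifest(out_dir / "manifest.jsonl", manifest)
    return manifest, gen_params
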