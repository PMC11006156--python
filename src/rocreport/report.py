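"""Sectioned analysis report with a pluggable interpretation transport.

The report has a fixed skeleton — a mandatory disclaimer first, then
Introduction; Results with Data Quality Checking, ROC Plot and
Performance Measures subsections; and Conclusion.  Each section's
narrative comes from dispatching a prompt to a transport: either a
remote chat-completion endpoint (never used in tests) or the built-in
offline stub, which produces deterministic template-based
interpretations so the whole pipeline runs with no network.

Default (v1) prompts are filled from the analysis results using the
column names verbatim; custom (v2) prompts are user templates with the
same named placeholders.  By default the two data-quality prompts are
merged into one dispatch so a full report costs five transport calls;
``merge_data_quality=False`` switches to six separate calls.
"""

from __future__ import annotations

import base64
import datetime
import json
import os
import re
import urllib.request
from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import RenderError, TemplateError, TransportConfigError
from .metrics import PerformanceTable

DISCLAIMER = (
    "Disclaimer: the narrative sections of this report were generated "
    "automatically and may contain misinterpretations. They are not medical "
    "advice; verify every statement against the numerical output before use. "
    "Note also that the minimum-p-value cutoff method inflates the Type I "
    "error rate because no multiplicity correction is applied."
)

#: Fixed timestamp recorded by deterministic transports, so that offline
#: prompt logs are byte-identical across runs.
EPOCH_TIMESTAMP = "1970-01-01T00:00:00Z"

SECTION_ORDER = (
    "introduction",
    "distribution",
    "class_distribution",
    "roc_plot",
    "performance",
    "conclusion",
)


@dataclass
class PromptSet:
    """One text template (or filled prompt) per report section."""

    introduction: str = ""
    distribution: str = ""
    class_distribution: str = ""
    roc_plot: str = ""
    performance: str = ""
    conclusion: str = ""

    def as_dict(self) -> dict[str, str]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Version-1 built-in templates.  Placeholders are filled from the analysis
#: results; column names are used verbatim so interpretations refer to the
#: user's own variable names.
DEFAULT_PROMPTS = PromptSet(
    introduction=(
        "Write an introduction paragraph for a diagnostic accuracy report. "
        "We are conducting an ROC curve analysis for {outcome}. Our chosen "
        "biomarker is {marker}, and the binary outcome under study is "
        "{outcome}. We have obtained an AUC value of {auc}, and the optimal "
        "cutoff value has been identified as {threshold}."
    ),
    distribution=(
        "We are conducting an ROC curve analysis on {marker} in association "
        "with {outcome}. Analyse the distribution of this variable. The mean "
        "stands at {mean}, the standard deviation at {sd}, the median at "
        "{median}, with a range from a minimum value of {minimum} to a "
        "maximum of {maximum} and mode {mode}."
    ),
    class_distribution=(
        "We are studying the biomarker {marker} in relation to a binary "
        "outcome variable {outcome} with classes {pos_label} and {neg_label}. "
        "For {marker} in the {pos_label} class the statistics are: a mean "
        "value of {pos_mean}, a minimum value of {pos_min}, and a maximum "
        "value of {pos_max}. In contrast, for the {neg_label} class, the mean "
        "is {neg_mean}, the minimum is {neg_min}, and the maximum is "
        "{neg_max}. Based on this information, interpret these two classes."
    ),
    roc_plot=(
        "We are undertaking an ROC curve analysis focusing on {marker} in the "
        "context of {outcome}, achieving an AUC of {auc}. Provide your "
        "detailed interpretation of the ROC plot's implications."
    ),
    performance=(
        "Interpret the results of the ROC biomarker analysis based on the "
        "following data: Threshold: {threshold}, Sensitivity: {sensitivity}, "
        "Specificity: {specificity}, and Accuracy: {accuracy}."
    ),
    conclusion=(
        "Write a Conclusion section. In this research, we conducted a "
        "Receiver Operating Characteristic (ROC) curve analysis to determine "
        "the optimal cut-off points for the {marker} biomarker in relation "
        "to {outcome}. For your conclusion, consider integrating the "
        "following key findings: the AUC is {auc}, and the recommended "
        "threshold for the {marker} biomarker is {threshold}."
    ),
)

_PLACEHOLDER_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*)\}")


def fill_template(template: str, context: dict) -> str:
    """Substitute {name} placeholders; unknown names raise TemplateError."""
    missing = sorted(
        {m.group(1) for m in _PLACEHOLDER_RE.finditer(template)} - set(context)
    )
    if missing:
        raise TemplateError(f"unresolved placeholder(s): {', '.join(missing)}")
    return template.format(**{k: context[k] for k in context})


def build_prompts(context: dict, custom: PromptSet | None = None) -> PromptSet:
    """Fill the section prompts from the analysis ``context``.

    v1 behaviour: no ``custom`` set, the built-in templates are used.  v2:
    each non-empty custom slot replaces the default; empty slots fall back.
    """
    filled = {}
    for name in SECTION_ORDER:
        template = getattr(custom, name, "") if custom is not None else ""
        if not template:
            template = getattr(DEFAULT_PROMPTS, name)
        filled[name] = fill_template(template, context)
    return PromptSet(**filled)


# ---------------------------------------------------------------------------
# transports

class OfflineTransport:
    """Deterministic no-network transport.

    Returns a canned, readable interpretation assembled purely from the
    section name and the prompt text, so repeated runs produce identical
    bytes.
    """

    name = "offline"
    deterministic = True

    _LEADS = {
        "introduction": "This report evaluates a continuous biomarker "
                        "against a binary outcome using ROC curve analysis.",
        "data_quality": "The biomarker's pooled and per-class distributions "
                        "were inspected before the ROC analysis.",
        "distribution": "The pooled distribution of the biomarker was "
                        "inspected before the ROC analysis.",
        "class_distribution": "The biomarker's distribution was compared "
                              "between the two outcome classes.",
        "roc_plot": "The ROC curve summarizes the sensitivity/specificity "
                    "trade-off across all candidate cutoffs.",
        "performance": "The table reports the diagnostic performance at the "
                       "selected cutoff.",
        "conclusion": "Overall, the analysis identifies a single recommended "
                      "cutoff for the biomarker.",
    }

    def __call__(self, prompt: str, section: str = "") -> str:
        lead = self._LEADS.get(section, "Automated interpretation.")
        numbers = re.findall(r"-?\d+\.?\d*", prompt)
        tail = (
            " Key values supplied: " + ", ".join(numbers) + "."
            if numbers else ""
        )
        return f"{lead} (Offline interpretation; no language model was consulted.){tail}"


class RemoteTransport:
    """Chat-completion transport over HTTP (stdlib urllib).

    The API key is read from the environment only — never from config
    files or logs.  This transport is optional plumbing for interactive
    use and is not exercised by the test suite.
    """

    deterministic = False

    def __init__(
        self,
        model: str = "gpt-3.5-turbo",
        endpoint: str = "https://api.openai.com/v1/chat/completions",
        api_key_env: str = "OPENAI_API_KEY",
        timeout: float = 60.0,
    ):
        self.model = model
        self.endpoint = endpoint
        self.api_key_env = api_key_env
        self.timeout = timeout
        self.name = f"remote:{model}"

    def __call__(self, prompt: str, section: str = "") -> str:
        key = os.environ.get(self.api_key_env)
        if not key:
            raise TransportConfigError(
                f"environment variable {self.api_key_env} is not set"
            )
        payload = json.dumps(
            {"model": self.model,
             "messages": [{"role": "user", "content": prompt}]}
        ).encode()
        req = urllib.request.Request(
            self.endpoint,
            data=payload,
            headers={"Content-Type": "application/json",
                     "Authorization": f"Bearer {key}"},
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            body = json.load(resp)
        return body["choices"][0]["message"]["content"]


def dispatch(
    prompts: PromptSet,
    transport,
    merge_data_quality: bool = True,
) -> list[dict]:
    """Send the section prompts through ``transport`` and log every exchange.

    With ``merge_data_quality`` (default) the distribution and
    class-distribution prompts are combined into a single data_quality
    call, for five calls per report; otherwise six calls are made.  A
    transport failure on one call degrades to a placeholder response for
    that section — the report is still rendered.
    """
    calls: list[tuple[str, str]] = [("introduction", prompts.introduction)]
    if merge_data_quality:
        calls.append(
            ("data_quality",
             prompts.distribution + "\n\n" + prompts.class_distribution)
        )
    else:
        calls.append(("distribution", prompts.distribution))
        calls.append(("class_distribution", prompts.class_distribution))
    calls += [
        ("roc_plot", prompts.roc_plot),
        ("performance", prompts.performance),
        ("conclusion", prompts.conclusion),
    ]

    deterministic = bool(getattr(transport, "deterministic", False))
    log: list[dict] = []
    for section, prompt in calls:
        entry = {
            "section": section,
            "prompt": prompt,
            "transport": getattr(transport, "name", type(transport).__name__),
            "timestamp": (
                EPOCH_TIMESTAMP if deterministic
                else datetime.datetime.now(datetime.timezone.utc)
                .strftime("%Y-%m-%dT%H:%M:%SZ")
            ),
        }
        try:
            entry["response"] = transport(prompt, section=section)
        except Exception as exc:  # degrade, don't abort
            entry["response"] = (
                "[Interpretation unavailable for this section: transport "
                "error. The numerical results above remain valid.]"
            )
            entry["error"] = str(exc)
        log.append(entry)
    return log


def write_prompt_log(log: list[dict], path) -> None:
    """JSON-lines prompt/response log (always on)."""
    with open(path, "w", encoding="utf-8") as fh:
        for entry in log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# rendering

@dataclass
class ReportSpec:
    """Everything needed to render a report."""

    title: str
    disclaimer: str
    prompt_log: list[dict]
    table: PerformanceTable | None = None
    figures: dict[str, str] = field(default_factory=dict)  # caption -> path


def _responses_by_section(log: list[dict]) -> dict[str, str]:
    return {e["section"]: e["response"] for e in log}


def _sections(spec: ReportSpec) -> list[tuple[int, str, str]]:
    """(heading level, heading, body) triples in fixed order."""
    resp = _responses_by_section(spec.prompt_log)
    if "data_quality" in resp:
        dq = [(3, "Data Quality Checking", resp["data_quality"])]
    else:
        dq = [
            (3, "Data Quality Checking",
             resp.get("distribution", "") + "\n\n"
             + resp.get("class_distribution", "")),
        ]
    table_text = spec.table.render_text() if spec.table is not None else ""
    return [
        (1, "Introduction", resp.get("introduction", "")),
        (1, "Results", ""),
        *dq,
        (3, "ROC Plot", resp.get("roc_plot", "")),
        (3, "Performance Measures",
         (("```\n" + table_text + "\n```\n\n") if table_text else "")
         + resp.get("performance", "")),
        (1, "Conclusion", resp.get("conclusion", "")),
    ]


_FIGURE_SECTION = {  # which section each well-known figure belongs under
    "distribution": "Data Quality Checking",
    "class_distribution": "Data Quality Checking",
    "roc": "ROC Plot",
}


def render_report(spec: ReportSpec, out_path, format: str = "html") -> Path:
    """Render the report as self-contained HTML or Markdown + assets.

    Refuses a spec without a disclaimer; a missing figure file raises
    RenderError naming the file.
    """
    if not spec.disclaimer or not spec.disclaimer.strip():
        raise RenderError("report spec has no disclaimer; refusing to render")
    out_path = Path(out_path)
    # Relative figure paths are resolved against the report's directory so
    # Markdown output can reference sibling assets and stay byte-identical
    # across runs in different output directories.
    base = out_path.parent
    resolved: dict[str, Path] = {}
    for name, fpath in spec.figures.items():
        p = Path(fpath)
        if not p.is_absolute():
            p = base / p
        if not p.is_file():
            raise RenderError(f"figure file missing: {fpath} ({name})")
        resolved[name] = p
    if format == "markdown":
        text = _render_markdown(spec)
    elif format == "html":
        text = _render_html(spec, resolved)
    else:
        raise ValueError("format must be 'html' or 'markdown'")
    out_path.write_text(text, encoding="utf-8")
    return out_path


def _figures_for(spec: ReportSpec, heading: str) -> list[tuple[str, str]]:
    return [
        (name, path) for name, path in spec.figures.items()
        if _FIGURE_SECTION.get(name) == heading
    ]


def _render_markdown(spec: ReportSpec) -> str:
    lines = [f"# {spec.title}", "", f"> {spec.disclaimer}", ""]
    for level, heading, body in _sections(spec):
        lines.append("#" * level + " " + heading)
        lines.append("")
        for name, fpath in _figures_for(spec, heading):
            lines.append(f"![{name}]({fpath})")
            lines.append("")
        if body:
            lines.append(body)
            lines.append("")
    return "\n".join(lines)


def _render_html(spec: ReportSpec, resolved: dict[str, Path]) -> str:
    def esc(s: str) -> str:
        return (s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{esc(spec.title)}</title>",
        "<style>body{font-family:sans-serif;max-width:50em;margin:2em auto;}"
        "blockquote{background:#fff3cd;padding:1em;border-left:4px solid #f0ad4e;}"
        "pre{background:#f6f8fa;padding:1em;overflow-x:auto;}"
        "img{max-width:100%;}</style></head><body>",
        f"<h1>{esc(spec.title)}</h1>",
        f"<blockquote>{esc(spec.disclaimer)}</blockquote>",
    ]
    for level, heading, body in _sections(spec):
        parts.append(f"<h{level + 1}>{esc(heading)}</h{level + 1}>")
        for name, fpath in _figures_for(spec, heading):
            fpath = resolved[name]
            data = base64.b64encode(Path(fpath).read_bytes()).decode()
            suffix = Path(fpath).suffix.lstrip(".").lower()
            mime = "image/svg+xml" if suffix == "svg" else f"image/{suffix}"
            parts.append(f"<img alt='{esc(name)}' src='data:{mime};base64,{data}'>")
        if body:
            for chunk in body.split("\n\n"):
                if chunk.startswith("```") :
                    parts.append("<pre>" + esc(chunk.strip("`\n")) + "</pre>")
                elif chunk.strip():
                    parts.append(f"<p>{esc(chunk)}</p>")
    parts.append("</body></html>")
    return "\n".join(parts)
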