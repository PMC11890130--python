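"""Strip boilerplate from a web page and segment the body into sentences.

The stopword-density heuristic keeps prose paragraphs and drops
navigation, footers and link lists; the segmenter is rule-based so the
same page always yields the same sentence spans.
"""

import healthfact as hf

HTML = """
<html><body>
  <nav><a href="/">Home</a> <a href="/topics">Topics</a> <a href="/contact">Contact</a></nav>
  <p>Hypertension is a common condition in which the force of the blood against
     the artery walls is too high over a long period of time.</p>
  <p>The prevalence was 0.24% in 2014. It is usually diagnosed with repeated
     readings that are taken by a doctor during several separate visits.</p>
  <footer><a href="/privacy">Privacy</a> <a href="/terms">Terms</a></footer>
</body></html>
"""

text = hf.extract_main_text(HTML)
print("--- main text (navigation and footer removed) ---")
print(text)

sentences = hf.segment_sentences(text, doc_id="demo")
print(f"\n--- {len(sentences)} sentences (note: the decimal 0.24 is not a boundary) ---")
for s in sentences:
    print(f"{s.sent_id}  [{s.char_span[0]}:{s.char_span[1]}]  {s.text}")
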