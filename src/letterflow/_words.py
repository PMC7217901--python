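"""Compact built-in English word list, ordered by approximate frequency rank.

Used (a) to derive the shipped letter-bigram frequency table and (b) as the
vocabulary the synthetic-session generator samples target words from.  The
list covers the ~300 highest-frequency English words plus a tail of common
content words; weights are assigned by Zipf's law (weight ~ 1/rank), which
is adequate for orthographic-regularity statistics such as relative bigram
frequencies (e.g. "nt" vastly outnumbering "tn").  It is an approximation
of corpus norms, not a redistribution of any published table.
"""

WORDS = [
    "the", "be", "to", "of", "and", "a", "in", "that", "have", "i",
    "it", "for", "not", "on", "with", "he", "as", "you", "do", "at",
    "this", "but", "his", "by", "from", "they", "we", "say", "her", "she",
    "or", "an", "will", "my", "one", "all", "would", "there", "their", "what",
    "so", "up", "out", "if", "about", "who", "get", "which", "go", "me",
    "when", "make", "can", "like", "time", "no", "just", "him", "know", "take",
    "people", "into", "year", "your", "good", "some", "could", "them", "see", "other",
    "than", "then", "now", "look", "only", "come", "its", "over", "think", "also",
    "back", "after", "use", "two", "how", "our", "work", "first", "well", "way",
    "even", "new", "want", "because", "any", "these", "give", "day", "most", "us",
    "is", "was", "are", "has", "had", "were", "said", "did", "been", "more",
    "where", "very", "through", "down", "should", "still", "such", "here", "own", "while",
    "might", "again", "world", "life", "never", "under", "last", "right", "thing", "around",
    "before", "great", "same", "another", "between", "each", "those", "much", "too", "need",
    "feel", "three", "state", "off", "really", "something", "why", "turn", "hand", "high",
    "every", "leave", "point", "find", "tell", "ask", "seem", "help", "show", "play",
    "small", "end", "put", "home", "read", "long", "little", "house", "old", "big",
    "word", "letter", "water", "call", "part", "place", "made", "live", "sound", "name",
    "sentence", "man", "line", "differ", "cause", "mean", "move", "boy", "follow", "came",
    "many", "number", "oil", "sit", "stand", "both", "paper", "together", "got", "group",
    "often", "run", "important", "until", "side", "began", "grow", "open", "walk", "example",
    "began", "start", "story", "earth", "father", "head", "page", "country", "found", "answer",
    "school", "study", "learn", "plant", "cover", "food", "sun", "four", "keep", "eye",
    "light", "thought", "let", "tree", "cross", "hard", "draw", "left", "late", "real",
    "few", "north", "book", "carry", "took", "science", "eat", "room", "friend", "idea",
    "fish", "mountain", "stop", "once", "base", "hear", "horse", "cut", "sure", "watch",
    "color", "face", "wood", "main", "enough", "plain", "girl", "usual", "young", "ready",
    "above", "ever", "red", "list", "though", "bird", "soon", "body", "dog", "family",
    "direct", "pose", "song", "measure", "door", "product", "black", "short", "class", "wind",
    "question", "happen", "complete", "ship", "area", "half", "rock", "order", "fire", "south",
    "problem", "piece", "told", "knew", "pass", "since", "whole", "king", "space", "heard",
    "best", "hour", "better", "true", "during", "hundred", "five", "remember", "step", "early",
    "hold", "west", "ground", "interest", "reach", "fast", "verb", "sing", "listen", "six",
    "table", "travel", "less", "morning", "ten", "simple", "several", "vowel", "toward", "war",
    "lay", "against", "pattern", "slow", "center", "love", "person", "money", "serve", "appear",
    "road", "map", "rain", "rule", "govern", "pull", "cold", "notice", "voice", "unit",
    "power", "town", "fine", "certain", "fly", "fall", "lead", "cry", "dark", "machine",
    "note", "wait", "plan", "figure", "star", "box", "noun", "field", "rest", "correct",
    "able", "pound", "done", "beauty", "drive", "stood", "contain", "front", "teach", "week",
    "final", "gave", "green", "quick", "develop", "ocean", "warm", "free", "minute", "strong",
    "special", "mind", "behind", "clear", "tail", "produce", "fact", "street", "inch", "multiply",
    "nothing", "course", "stay", "wheel", "full", "force", "blue", "object", "decide", "surface",
    "deep", "moon", "island", "foot", "system", "busy", "test", "record", "boat", "common",
    "gold", "possible", "plane", "dry", "wonder", "laugh", "thousand", "ago", "ran", "check",
    "game", "shape", "yes", "hot", "miss", "brought", "heat", "snow", "bed", "bring",
    "flower", "explore", "waiting", "decade", "garden", "sunflower", "corpse", "island", "discover", "spell",
]


def zipf_weights():
    """(word, weight) pairs with Zipf weight 1/rank, duplicates merged."""
    seen = {}
    for rank, w in enumerate(WORDS, start=1):
        if w not in seen:
            seen[w] = 1.0 / rank
    return list(seen.items())
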