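# Dialect inventory for rendering anthropometric statements in posts.
# version: 1
# Each field lists unambiguous templates (which the rule-based extractor is
# guaranteed to parse back exactly) and one ambiguous template (a rendering
# that a precision-first extractor deliberately refuses to parse, e.g. a
# weight with no unit suffix).  Placeholders: {age}, {gender_word}, {weight}
# (pounds), {feet}, {inches}, {total_inches}.
version: 1
fields:
  weight:
    unambiguous:
      - id: pounds
        template: "I weigh {weight} pounds"
      - id: lbs
        template: "I weigh {weight} lbs"
      - id: lb_my_weight
        template: "my weight is {weight} lbs"
    ambiguous:
      id: bare_number
      template: "I weigh {weight}"
  height:
    unambiguous:
      - id: foot_inches
        template: "am {feet} foot {inches} inches tall"
      - id: apostrophe
        template: "I'm {feet}'{inches}\""
      - id: ft_in
        template: "I am {feet} ft {inches} in"
      - id: foot_bare
        template: "I am {feet} foot {inches}"
    ambiguous:
      id: bare_total
      template: "I'm around {total_inches} tall"
  age:
    unambiguous:
      - id: years_old
        template: "{age} years old"
      - id: i_am_years_old
        template: "I am {age} years old"
      - id: i_am
        template: "I am {age}"
    ambiguous:
      id: turned
      template: "just turned {age}"
  gender:
    unambiguous:
      - id: a_gender
        template: "I am a {gender_word}"
      - id: im_gender
        template: "I'm a {gender_word}"
    ambiguous:
      id: person
      template: "I'm just a person"
gender_words:
  male: ["male", "boy", "guy", "man"]
  female: ["female", "girl", "woman"]
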